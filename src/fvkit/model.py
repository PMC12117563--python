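"""Hierarchical structure container: Atom / Residue / Chain / StructureModel.

This is the substrate every pipeline stage operates on.  It is deliberately
small: a first-model, polymer-only, alt-loc-collapsed view of a PDB/mmCIF
entry, plus the experimental metadata (method, resolution) that the dataset
profiler consumes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "StructureMetadata",
    "ResidueId",
    "STANDARD_AA3",
    "THREE_TO_ONE",
]

#: (seq_number, insertion_code) — the key a residue is addressed by within a chain.
ResidueId = tuple[int, str]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
STANDARD_AA3 = frozenset(THREE_TO_ONE)

_ENTRY_ID_RE = re.compile(r"^[A-Za-z0-9]{4}$")


@dataclass
class Atom:
    """One heavy (or hydrogen) atom.

    Coordinates are Cartesian, in Angstroms.  ``alt_loc`` is the surviving
    alternate-location indicator after highest-occupancy collapse ("" when
    the atom had a single conformation).
    """

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    alt_loc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,):
            raise ValueError(f"atom coord must be a 3-vector, got {self.coord.shape}")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinate for atom {self.name!r}")
        if not self.name:
            raise ValueError("atom name must be non-empty")

    def copy(self) -> "Atom":
        return replace(self, coord=self.coord.copy())


@dataclass
class Residue:
    """An amino-acid residue keyed by (seq_number, insertion_code)."""

    res_name: str
    seq_number: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def rid(self) -> ResidueId:
        return (self.seq_number, self.insertion_code)

    @property
    def is_standard(self) -> bool:
        return self.res_name in STANDARD_AA3

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Optional[Atom]:
        return self.atom("CA")

    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")

    def copy(self) -> "Residue":
        return Residue(self.res_name, self.seq_number, self.insertion_code,
                       [a.copy() for a in self.atoms])


@dataclass
class Chain:
    """Ordered residues under one single-character chain identifier."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[ResidueId] = set()
        for r in self.residues:
            if r.rid in seen:
                raise ValueError(
                    f"duplicate residue {r.rid} in chain {self.chain_id!r}")
            seen.add(r.rid)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def get(self, seq_number: int, insertion_code: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.seq_number == seq_number and r.insertion_code == insertion_code:
                return r
        return None

    def sequence(self) -> str:
        """One-letter sequence over the chain's residues ('X' for non-standard)."""
        return "".join(r.one_letter() for r in self.residues)

    def atoms(self) -> Iterator[Atom]:
        for r in self.residues:
            yield from r.atoms

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


@dataclass
class StructureMetadata:
    """Experimental provenance: determination method and resolution (A)."""

    method: str = "unknown"  # xray | em | nmr | other | unknown
    resolution: Optional[float] = None

    _METHODS = ("xray", "em", "nmr", "other", "unknown")

    def __post_init__(self) -> None:
        if self.method not in self._METHODS:
            raise ValueError(f"unknown method class {self.method!r}")
        if self.resolution is not None and not self.resolution > 0:
            raise ValueError("resolution must be positive when present")


@dataclass
class StructureModel:
    """One structure entry: a 4-character id, its chains and metadata."""

    entry_id: str
    chains: list[Chain] = field(default_factory=list)
    metadata: StructureMetadata = field(default_factory=StructureMetadata)

    def __post_init__(self) -> None:
        if not _ENTRY_ID_RE.match(self.entry_id):
            raise ValueError(f"entry_id must be 4 alphanumerics, got {self.entry_id!r}")
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chain ids in {self.entry_id}: {ids}")

    def chain(self, chain_id: str) -> Optional[Chain]:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def atoms(self) -> Iterator[Atom]:
        for c in self.chains:
            yield from c.atoms()

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def subset(self, chain_ids: Iterable[str]) -> "StructureModel":
        """Deep-copied model restricted to the given chains (given order)."""
        wanted = list(chain_ids)
        chains = []
        for cid in wanted:
            c = self.chain(cid)
            if c is None:
                raise KeyError(f"no chain {cid!r} in {self.entry_id}")
            chains.append(c.copy())
        return StructureModel(self.entry_id, chains, replace(self.metadata))

    def copy(self) -> "StructureModel":
        return StructureModel(self.entry_id, [c.copy() for c in self.chains],
                              replace(self.metadata))


def coords_of(residues: Iterable[Residue], atom_names: Optional[Iterable[str]] = None) -> np.ndarray:
    """Stacked (n, 3) coordinates of the named atoms over ``residues``.

    With ``atom_names`` None all atoms are taken; otherwise atoms are taken
    in the given name order per residue, skipping absent ones.
    """
    out = []
    names = list(atom_names) if atom_names is not None else None
    for r in residues:
        if names is None:
            out.extend(a.coord for a in r.atoms)
        else:
            for nm in names:
                a = r.atom(nm)
                if a is not None:
                    out.append(a.coord)
    if not out:
        return np.zeros((0, 3))
    return np.vstack(out)
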