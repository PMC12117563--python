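"""Read/write protein structures and enforce atom-completeness rules.

Reading goes through gemmi (PDB and mmCIF); only the first model is kept,
alternate locations are collapsed to the highest-occupancy conformer,
and waters plus non-polymer heteroatoms are dropped.  Writing emits
fixed-column PDB text that round-trips through :func:`read_structure`
(coordinates to 3 decimals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import gemmi

from .model import (Atom, Chain, Residue, StructureMetadata, StructureModel,
                    STANDARD_AA3)

__all__ = [
    "read_structure",
    "write_structure",
    "check_atom_completeness",
    "CompletenessViolation",
    "StructureParseError",
    "EmptyStructureError",
    "HEAVY_ATOMS",
]

log = logging.getLogger(__name__)


class StructureParseError(ValueError):
    """File could not be parsed as PDB or mmCIF."""


class EmptyStructureError(ValueError):
    """File parsed but contained no polymer residues."""


# Backbone + side-chain heavy atoms for the 20 standard residues (OXT and
# hydrogens deliberately excluded from completeness checking).
_BB = ("N", "CA", "C", "O")
HEAVY_ATOMS: dict[str, frozenset[str]] = {
    "ALA": frozenset(_BB + ("CB",)),
    "ARG": frozenset(_BB + ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2")),
    "ASN": frozenset(_BB + ("CB", "CG", "OD1", "ND2")),
    "ASP": frozenset(_BB + ("CB", "CG", "OD1", "OD2")),
    "CYS": frozenset(_BB + ("CB", "SG")),
    "GLN": frozenset(_BB + ("CB", "CG", "CD", "OE1", "NE2")),
    "GLU": frozenset(_BB + ("CB", "CG", "CD", "OE1", "OE2")),
    "GLY": frozenset(_BB),
    "HIS": frozenset(_BB + ("CB", "CG", "ND1", "CD2", "CE1", "NE2")),
    "ILE": frozenset(_BB + ("CB", "CG1", "CG2", "CD1")),
    "LEU": frozenset(_BB + ("CB", "CG", "CD1", "CD2")),
    "LYS": frozenset(_BB + ("CB", "CG", "CD", "CE", "NZ")),
    "MET": frozenset(_BB + ("CB", "CG", "SD", "CE")),
    "PHE": frozenset(_BB + ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ")),
    "PRO": frozenset(_BB + ("CB", "CG", "CD")),
    "SER": frozenset(_BB + ("CB", "OG")),
    "THR": frozenset(_BB + ("CB", "OG1", "CG2")),
    "TRP": frozenset(_BB + ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3",
                            "CZ2", "CZ3", "CH2")),
    "TYR": frozenset(_BB + ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH")),
    "VAL": frozenset(_BB + ("CB", "CG1", "CG2")),
}

_METHOD_MAP = {
    "X-RAY DIFFRACTION": "xray",
    "ELECTRON MICROSCOPY": "em",
    "ELECTRON CRYSTALLOGRAPHY": "em",
    "SOLUTION NMR": "nmr",
    "SOLID-STATE NMR": "nmr",
}


def _classify_method(raw: str) -> str:
    raw = raw.strip().upper()
    if not raw:
        return "unknown"
    for key, val in _METHOD_MAP.items():
        if key in raw:
            return val
    return "other"


def _entry_id_from(st: gemmi.Structure, path: Path) -> str:
    info = dict(st.info)
    eid = info.get("_entry.id", "").strip()
    if len(eid) == 4 and eid.isalnum():
        return eid
    stem = path.stem.split("_")[0]
    if len(stem) >= 4 and stem[:4].isalnum():
        return stem[:4]
    return "XXXX"


def read_structure(path: Union[str, Path], format_hint: Optional[str] = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model is used.  Alternate locations are collapsed to the
    highest-occupancy atom (ties broken by alt-loc letter).  Waters and
    non-polymer heteroatoms (ligands, ions) are excluded; polymer-linked
    modified residues are retained.

    Parameters
    ----------
    path : str or Path
        Input file.
    format_hint : {"pdb", "cif", None}
        Force a format instead of inferring from the extension/content.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if format_hint == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format_hint in ("cif", "mmcif"):
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    st.setup_entities()

    metadata = StructureMetadata(
        method=_classify_method(dict(st.info).get("_exptl.method", "")),
        resolution=st.resolution if st.resolution and st.resolution > 0 else None,
    )
    entry_id = _entry_id_from(st, path)

    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    first = st[0]

    chains: list[Chain] = []
    for gchain in first:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.name == "HOH" or gres.is_water():
                continue
            if gres.entity_type not in (gemmi.EntityType.Polymer,
                                        gemmi.EntityType.Unknown):
                continue
            if gres.entity_type == gemmi.EntityType.Unknown and gres.het_flag == "H":
                # unassigned heteroatom outside the polymer: ligand/ion
                continue
            atoms = _collapse_altlocs(gres)
            if not atoms:
                continue
            residues.append(Residue(gres.name, gres.seqid.num,
                                    gres.seqid.icode.strip(), atoms))
        if residues:
            cid = gchain.name[:1] if gchain.name else "A"
            residues = _dedupe(residues, cid)
            chains.append(Chain(cid, residues))
    if not chains:
        raise EmptyStructureError(f"{path}: no polymer residues")
    return StructureModel(entry_id, chains, metadata)


def _collapse_altlocs(gres: gemmi.Residue) -> list[Atom]:
    best: dict[str, Atom] = {}
    order: list[str] = []
    for ga in gres:
        alt = ga.altloc if ga.altloc not in ("", "\0", " ") else ""
        atom = Atom(
            name=ga.name,
            element=ga.element.name.upper(),
            coord=(ga.pos.x, ga.pos.y, ga.pos.z),
            occupancy=ga.occ,
            b_factor=ga.b_iso,
            alt_loc=alt,
        )
        prev = best.get(ga.name)
        if prev is None:
            best[ga.name] = atom
            order.append(ga.name)
        elif (atom.occupancy, _alt_rank(atom.alt_loc)) > (
                prev.occupancy, _alt_rank(prev.alt_loc)):
            best[ga.name] = atom
    return [best[n] for n in order]


def _alt_rank(alt: str) -> int:
    # higher rank wins ties: '' > 'A' > 'B' > ...
    return 0 if not alt else -ord(alt)


def _dedupe(residues: list[Residue], chain_id: str) -> list[Residue]:
    seen: set = set()
    out = []
    for r in residues:
        if r.rid in seen:
            log.warning("chain %s: dropping duplicate residue %s", chain_id, r.rid)
            continue
        seen.add(r.rid)
        out.append(r)
    return out


def _format_atom_name(name: str, element: str) -> str:
    """PDB columns 13-16: element right-justified in 13-14 for short names."""
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and not name[:1].isdigit():
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_structure(model: StructureModel, path: Union[str, Path]) -> None:
    """Serialize a model as fixed-column PDB text.

    Re-reading the file yields an equal model (names, numbers, coordinates
    to 3 decimals).  Chain ids must be single characters.
    """
    for c in model.chains:
        if len(c.chain_id) != 1:
            raise ValueError(
                f"PDB chain id must be one character, got {c.chain_id!r}")
    lines = [f"HEADER    {'':40s}{'':9s}   {model.entry_id.upper():<4s}"]
    expdta = {"xray": "X-RAY DIFFRACTION", "em": "ELECTRON MICROSCOPY",
              "nmr": "SOLUTION NMR"}.get(model.metadata.method)
    if expdta:
        lines.append(f"EXPDTA    {expdta}")
    if model.metadata.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {model.metadata.resolution:7.2f} ANGSTROMS.")
    serial = 0
    for chain in model.chains:
        last = None
        for res in chain:
            record = "ATOM  " if res.is_standard else "HETATM"
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.coord
                lines.append(
                    f"{record}{min(serial, 99999):5d} "
                    f"{_format_atom_name(atom.name, atom.element)}"
                    f"{atom.alt_loc or ' ':1s}"
                    f"{res.res_name:>3s} {chain.chain_id}"
                    f"{res.seq_number:4d}{res.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}          "
                    f"{atom.element:>2s}")
            last = res
        if last is not None:
            serial += 1
            lines.append(
                f"TER   {min(serial, 99999):5d}      {last.res_name:>3s} "
                f"{chain.chain_id}{last.seq_number:4d}{last.insertion_code or ' ':1s}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class CompletenessViolation:
    """A residue missing part of its expected heavy-atom set."""

    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    missing: frozenset[str]

    def __str__(self) -> str:
        miss = ",".join(sorted(self.missing))
        return (f"{self.chain_id}/{self.res_name}{self.seq_number}"
                f"{self.insertion_code}: missing {{{miss}}}")


def check_atom_completeness(model: StructureModel) -> list[CompletenessViolation]:
    """Report every standard residue missing heavy atoms.

    Non-standard (modified) residues are exempt.  An empty list means the
    structure passes the missing-atom filter.  The check is report-only;
    callers decide whether to reject the whole entry.
    """
    violations: list[CompletenessViolation] = []
    for chain in model.chains:
        for res in chain:
            expected = HEAVY_ATOMS.get(res.res_name)
            if expected is None:
                continue
            present = {a.name for a in res.atoms}
            missing = expected - present
            if missing:
                violations.append(CompletenessViolation(
                    chain.chain_id, res.seq_number, res.insertion_code,
                    res.res_name, frozenset(missing)))
    return violations
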