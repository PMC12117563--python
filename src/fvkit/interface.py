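"""Docking-preparation computations: renumbering and restraint lists.

Produces the inputs a data-driven docking run needs: sequentially
renumbered antibody chains (heavy from 1, light from 500 so the two never
overlap), and active/passive residue lists — CDR residues are active on
the antibody side; on the antigen side either every solvent-exposed
residue is passive (blind mode) or the epitope found by the SASA change
upon complexation is active (site-directed mode).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .annotation import NumberedDomain, cdr_residues
from .descriptors import relative_sasa, sasa
from .model import Chain, Residue, ResidueId, StructureModel

__all__ = [
    "LIGHT_CHAIN_START",
    "RestraintSet",
    "renumber_for_docking",
    "antibody_active",
    "antigen_passive_surface",
    "epitope_by_delta_sasa",
    "write_restraints",
]

LIGHT_CHAIN_START = 500

ResRef = tuple[str, int, str]  # (chain_id, seq_number, insertion_code)


@dataclass
class RestraintSet:
    """Active/passive residue lists for one docking partner."""

    partner: str                       # "antibody" | "antigen"
    active: list[ResRef] = field(default_factory=list)
    passive: list[ResRef] = field(default_factory=list)
    delta_sasa: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        overlap = set(self.active) & set(self.passive)
        if overlap:
            raise ValueError(f"residues both active and passive: {sorted(overlap)}")


def renumber_for_docking(heavy: Chain, light: Optional[Chain] = None,
                         light_start: int = LIGHT_CHAIN_START
                         ) -> tuple[list[Chain], dict[str, dict[ResidueId, int]]]:
    """Renumber antibody chains sequentially for docking input.

    The heavy chain runs 1..n with no insertion codes; the light chain
    starts at ``light_start`` so numbers never overlap.  Returns the new
    chains plus, per chain id, the original-to-new number mapping (a
    bijection, so the original numbering can be restored).
    """
    if len(heavy) >= light_start:
        raise ValueError(
            f"heavy chain of {len(heavy)} residues would collide with the "
            f"light-chain offset {light_start}")
    chains: list[Chain] = []
    mappings: dict[str, dict[ResidueId, int]] = {}

    def renum(chain: Chain, start: int) -> None:
        mapping: dict[ResidueId, int] = {}
        out: list[Residue] = []
        for i, res in enumerate(chain):
            new = start + i
            mapping[res.rid] = new
            out.append(Residue(res.res_name, new, "",
                               [a.copy() for a in res.atoms]))
        chains.append(Chain(chain.chain_id, out))
        mappings[chain.chain_id] = mapping

    renum(heavy, 1)
    if light is not None:
        renum(light, light_start)
    return chains, mappings


def antibody_active(domains: Sequence[NumberedDomain],
                    chains: dict[str, Chain]) -> RestraintSet:
    """Active residues of an antibody unit: the CDR residues of every domain.

    ``chains`` maps chain id to the Martin-renumbered chain of each
    domain.  The passive list is empty: the paratope is taken as known.
    """
    active: list[ResRef] = []
    for dom in domains:
        chain = chains[dom.chain_id]
        for res in cdr_residues(dom, chain):
            ref = (chain.chain_id, res.seq_number, res.insertion_code)
            if ref not in active:
                active.append(ref)
    return RestraintSet("antibody", active=active)


def antigen_passive_surface(antigen: StructureModel,
                            rsasa_threshold: float = 0.15,
                            probe_radius: float = 1.4,
                            n_sphere_points: int = 960) -> RestraintSet:
    """Blind-mode restraints: every surface-exposed antigen residue is passive.

    A residue is exposed when its relative SASA on the isolated antigen
    is at least ``rsasa_threshold``.  Residues with no reference area
    (non-standard) are included only at threshold 0.
    """
    sr = sasa(antigen, probe_radius, n_sphere_points)
    passive: list[ResRef] = []
    for chain in antigen.chains:
        for res in chain:
            area = sr.residue_area(chain.chain_id, res.rid)
            rel = relative_sasa(area, res.res_name)
            if rel is None:
                rel = 0.0
            if rel >= rsasa_threshold:
                passive.append((chain.chain_id, res.seq_number,
                                res.insertion_code))
    return RestraintSet("antigen", passive=passive)


def epitope_by_delta_sasa(complexed: StructureModel,
                          isolated: StructureModel,
                          min_delta: float = 1.0,
                          probe_radius: float = 1.4,
                          n_sphere_points: int = 960) -> RestraintSet:
    """Site-directed restraints: the epitope by SASA loss upon complexation.

    ``complexed`` holds the antigen in the context of the full complex;
    ``isolated`` the same antigen chains alone.  Residues losing more
    than ``min_delta`` A^2 of accessible area are active.  The two inputs
    must contain identical antigen residues.
    """
    iso_keys = {(c.chain_id, r.rid) for c in isolated.chains for r in c}
    com_keys = {(c.chain_id, r.rid)
                for c in complexed.chains if c.chain_id in
                {ch.chain_id for ch in isolated.chains}
                for r in c}
    if iso_keys != com_keys:
        raise ValueError(
            "antigen residues differ between complexed and isolated inputs")
    sr_com = sasa(complexed, probe_radius, n_sphere_points)
    sr_iso = sasa(isolated, probe_radius, n_sphere_points)
    active: list[ResRef] = []
    deltas: dict[str, float] = {}
    for chain in isolated.chains:
        for res in chain:
            key = (chain.chain_id, res.rid)
            delta = sr_iso.residue_area(*key) - sr_com.residue_area(*key)
            ref = (chain.chain_id, res.seq_number, res.insertion_code)
            deltas["{}/{}{}".format(*ref)] = round(float(delta), 3)
            if delta > min_delta:
                active.append(ref)
    return RestraintSet("antigen", active=active, delta_sasa=deltas)


def write_restraints(restraints: RestraintSet, path: Union[str, Path],
                     json_path: Optional[Union[str, Path]] = None) -> None:
    """Write a two-line active/passive residue list, plus a JSON manifest.

    Line 1 lists active residue numbers, line 2 passive ones — the plain
    text exchange format ambiguous-restraint docking tools consume.
    """
    def fmt(refs: list[ResRef]) -> str:
        return " ".join(f"{num}{ins}" for _, num, ins in refs)

    Path(path).write_text(fmt(restraints.active) + "\n"
                          + fmt(restraints.passive) + "\n")
    if json_path is not None:
        payload = {
            "partner": restraints.partner,
            "active": [list(r) for r in restraints.active],
            "passive": [list(r) for r in restraints.passive],
        }
        if restraints.delta_sasa:
            payload["delta_sasa"] = restraints.delta_sasa
        Path(json_path).write_text(json.dumps(payload, indent=1))
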