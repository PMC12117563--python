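"""Standardize antibody entries into one-complex-per-file records.

The stages mirror the curation flow: rename antibody chains (H/L, or h/l
for scFv), pair VH and VL domains by the conserved-cysteine Calpha
distance (Martin H92 vs L88, 22 A radius), resolve whether multi-chain
antigens are biological oligomers or crystal-packing neighbors, attach
each antibody unit to the antigen units its CDRs contact (Calpha pairs
within 7.5 A, at least one contact, antigens longer than 50 residues),
and emit ``XXXX_n`` files.  A dataset profiler summarizes experimental
metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .annotation import NumberedDomain, classify_format, renumber_to_martin
from .descriptors import sasa
from .model import (Chain, Residue, StructureMetadata, StructureModel,
                    coords_of)

__all__ = [
    "PAIRING_CUTOFF", "CONTACT_CUTOFF", "MIN_ANTIGEN_LEN",
    "VH_CYS_POSITION", "VL_CYS_POSITION",
    "FvPair", "AntibodyUnit", "AntigenUnit", "ComplexRecord",
    "pair_fv", "build_antibody_units",
    "default_interface_classifier", "classify_antigen_interfaces",
    "build_complexes", "rename_chains", "split_and_name",
    "profile_dataset", "DatasetProfile",
]

log = logging.getLogger(__name__)

PAIRING_CUTOFF = 22.0      # A, Cys92(VH)-Cys88(VL) Calpha radius
CONTACT_CUTOFF = 7.5       # A, CDR-antigen Calpha contact distance
MIN_ANTIGEN_LEN = 50       # residues; antigens must be strictly longer
VH_CYS_POSITION = (92, "")  # Martin position of the conserved VH cysteine
VL_CYS_POSITION = (88, "")  # Martin position of the conserved VL cysteine


@dataclass
class FvPair:
    """A VH/VL pair joined by conserved-cysteine proximity."""

    vh: NumberedDomain
    vl: NumberedDomain
    cys_distance: float

    def __post_init__(self) -> None:
        if self.vh.domain_type != "VH" or self.vl.domain_type != "VL":
            raise ValueError("FvPair requires a VH and a VL domain")


@dataclass
class AntibodyUnit:
    """One antibody entity: paired Fv, single domain, or scFv."""

    format: str                       # paired | heavy_only | light_only | scfv
    domains: list[NumberedDomain]
    cys_distance: Optional[float] = None

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for d in self.domains:
            if d.chain_id not in seen:
                seen.append(d.chain_id)
        return seen

    @property
    def sort_key(self) -> tuple:
        return tuple(sorted(self.chain_ids))


@dataclass
class AntigenUnit:
    """One antigen entity: a monomer chain or a biological oligomer."""

    chain_ids: list[str]
    oligomeric: bool = False

    def __post_init__(self) -> None:
        if self.oligomeric and len(self.chain_ids) < 2:
            raise ValueError("an oligomeric unit needs more than one chain")

    def n_residues(self, model: StructureModel) -> int:
        return sum(len(model.chain(cid) or []) for cid in self.chain_ids)


@dataclass
class ComplexRecord:
    """One output record: an antibody unit plus its antigen unit, if any."""

    antibody: AntibodyUnit
    antigen: Optional[AntigenUnit] = None
    contact_count: int = 0
    output_name: str = ""

    def __post_init__(self) -> None:
        if self.antigen is not None and self.contact_count < 1:
            raise ValueError("a complex record requires at least one contact")


def _cys_ca(domain: NumberedDomain, model: StructureModel,
            position: tuple[int, str]) -> Optional[np.ndarray]:
    rid = domain.original_of(position)
    if rid is None:
        return None
    chain = model.chain(domain.chain_id)
    if chain is None:
        return None
    res = chain.get(*rid)
    if res is None or res.ca is None:
        return None
    return res.ca.coord


def pair_fv(domains: Sequence[NumberedDomain], model: StructureModel,
            cutoff: float = PAIRING_CUTOFF
            ) -> tuple[list[FvPair], list[NumberedDomain]]:
    """Match VH to VL domains by conserved-cysteine Calpha distance.

    Greedy nearest-first matching under ``cutoff``: the globally closest
    eligible (VH, VL) pair is taken, both domains retired, and the process
    repeats (ties broken by chain-id order).  Domains that stay unmatched
    — or lack the conserved cysteine Calpha, which is logged — are
    returned as singles.  scFv domains (VH and VL on one chain) must be
    handled by the caller and not passed here.
    """
    vhs = [d for d in domains if d.domain_type == "VH"]
    vls = [d for d in domains if d.domain_type == "VL"]
    coords: dict[int, Optional[np.ndarray]] = {}
    for d in vhs:
        coords[id(d)] = _cys_ca(d, model, VH_CYS_POSITION)
    for d in vls:
        coords[id(d)] = _cys_ca(d, model, VL_CYS_POSITION)
    for d in vhs + vls:
        if coords[id(d)] is None:
            log.warning("chain %s (%s): conserved cysteine Calpha missing; "
                        "domain unpairable", d.chain_id, d.domain_type)

    candidates = []
    for h in vhs:
        for l in vls:
            ch, cl = coords[id(h)], coords[id(l)]
            if ch is None or cl is None:
                continue
            dist = float(np.linalg.norm(ch - cl))
            if dist <= cutoff:
                candidates.append((dist, h.chain_id, l.chain_id, h, l))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used: set[int] = set()
    pairs: list[FvPair] = []
    for dist, _, _, h, l in candidates:
        if id(h) in used or id(l) in used:
            continue
        used.add(id(h))
        used.add(id(l))
        pairs.append(FvPair(h, l, dist))
    singles = [d for d in vhs + vls if id(d) not in used]
    return pairs, singles


def build_antibody_units(domains: Sequence[NumberedDomain],
                         model: StructureModel,
                         cutoff: float = PAIRING_CUTOFF) -> list[AntibodyUnit]:
    """Group detected domains into antibody units.

    Chains carrying both a VH and a VL become scFv units; chains with two
    same-type domains are unusual and excluded (logged); the rest go
    through conserved-cysteine pairing.  Unusual entries are dropped here,
    matching the curation filter for uncommon formats.
    """
    by_chain: dict[str, list[NumberedDomain]] = {}
    for d in domains:
        by_chain.setdefault(d.chain_id, []).append(d)

    units: list[AntibodyUnit] = []
    pairable: list[NumberedDomain] = []
    for cid in sorted(by_chain):
        ds = by_chain[cid]
        fmt = classify_format({cid: ds})
        if fmt == "unusual":
            log.warning("chain %s has an uncommon domain arrangement; excluded", cid)
            continue
        if fmt == "scfv":
            units.append(AntibodyUnit("scfv", sorted(ds, key=lambda d: d.domain_type)))
        else:
            pairable.extend(ds)
    pairs, singles = pair_fv(pairable, model, cutoff)
    for p in pairs:
        units.append(AntibodyUnit("paired", [p.vh, p.vl], p.cys_distance))
    for s in singles:
        fmt = "heavy_only" if s.domain_type == "VH" else "light_only"
        units.append(AntibodyUnit(fmt, [s]))
    units.sort(key=lambda u: u.sort_key)
    return units


# ---------------------------------------------------------------------------
# Antigen oligomeric state

def default_interface_classifier(model: StructureModel, cid_a: str, cid_b: str,
                                 bsa_threshold: float = 800.0,
                                 min_contacts: int = 10,
                                 contact_dist: float = 5.5) -> bool:
    """Heuristic biological-vs-crystallographic interface call.

    An interface is biological when the buried surface area of the pair
    is at least ``bsa_threshold`` (A^2) AND at least ``min_contacts``
    residue pairs have heavy atoms within ``contact_dist``.  This is the
    default stand-in behind the pluggable classifier seam; an adapter to
    an external trained classifier can replace it.
    """
    a = model.subset([cid_a])
    b = model.subset([cid_b])
    ab = model.subset([cid_a, cid_b])
    # coarse sphere count keeps the heuristic fast; BSA needs no precision
    n_pts = 240
    bsa = (sum(sasa(a, n_sphere_points=n_pts).residue_areas.values())
           + sum(sasa(b, n_sphere_points=n_pts).residue_areas.values())
           - sum(sasa(ab, n_sphere_points=n_pts).residue_areas.values()))
    if bsa < bsa_threshold:
        return False
    ca_res = list(model.chain(cid_a))
    cb_res = list(model.chain(cid_b))
    n_contacts = 0
    for ra in ca_res:
        pa = coords_of([ra])
        for rb in cb_res:
            pb = coords_of([rb])
            d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1)
            if (d2 < contact_dist ** 2).any():
                n_contacts += 1
                if n_contacts >= min_contacts:
                    return True
    return False


InterfaceClassifier = Callable[[StructureModel, str, str], bool]


def classify_antigen_interfaces(model: StructureModel,
                                antigen_chain_ids: Sequence[str],
                                classifier: Optional[InterfaceClassifier] = None
                                ) -> list[AntigenUnit]:
    """Partition antigen chains into monomer and oligomer units.

    Chain pairs whose interface classifies biological are merged
    transitively into one oligomeric unit; everything else stays a
    monomer.  Classifier failures fall back to the conservative monomer
    treatment (logged).  The result is a partition: units are disjoint
    and cover every antigen chain.
    """
    cls = classifier or default_interface_classifier
    ids = sorted(antigen_chain_ids)
    parent = {c: c for c in ids}

    def find(c: str) -> str:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            try:
                biological = cls(model, a, b)
            except Exception as exc:
                log.warning("interface classifier failed on %s-%s (%s); "
                            "treating as crystallographic", a, b, exc)
                biological = False
            if biological:
                parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for c in ids:
        groups.setdefault(find(c), []).append(c)
    return [AntigenUnit(sorted(g), oligomeric=len(g) > 1)
            for g in sorted(groups.values())]


# ---------------------------------------------------------------------------
# Complex construction

def _cdr_ca_coords(unit: AntibodyUnit, model: StructureModel) -> np.ndarray:
    pts = []
    for dom in unit.domains:
        chain = model.chain(dom.chain_id)
        if chain is None:
            continue
        cdr_pos = set(dom.cdr_positions())
        for res in chain:
            pos = dom.number_map.get(res.rid)
            if pos in cdr_pos and res.ca is not None:
                pts.append(res.ca.coord)
    return np.vstack(pts) if pts else np.zeros((0, 3))


def _antigen_ca_coords(unit: AntigenUnit, model: StructureModel) -> np.ndarray:
    pts = []
    for cid in unit.chain_ids:
        chain = model.chain(cid)
        if chain is None:
            continue
        for res in chain:
            if res.ca is not None:
                pts.append(res.ca.coord)
    return np.vstack(pts) if pts else np.zeros((0, 3))


def count_cdr_contacts(unit: AntibodyUnit, antigen: AntigenUnit,
                       model: StructureModel,
                       cutoff: float = CONTACT_CUTOFF) -> int:
    """Number of (CDR residue, antigen residue) Calpha pairs closer than
    ``cutoff`` (strict inequality)."""
    a = _cdr_ca_coords(unit, model)
    b = _antigen_ca_coords(antigen, model)
    if len(a) == 0 or len(b) == 0:
        return 0
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
    return int((d2 < cutoff ** 2).sum())


def build_complexes(antibody_units: Sequence[AntibodyUnit],
                    antigen_units: Sequence[AntigenUnit],
                    model: StructureModel,
                    contact_cutoff: float = CONTACT_CUTOFF,
                    min_antigen_len: int = MIN_ANTIGEN_LEN
                    ) -> list[ComplexRecord]:
    """Attach each antibody unit to every antigen unit its CDRs contact.

    A complex needs at least one CDR-antigen Calpha contact and an
    antigen strictly longer than ``min_antigen_len`` residues (oligomer
    length summed over member chains).  Antibodies without a qualifying
    antigen are emitted once as free-antibody records; every input
    antibody unit appears in at least one record.
    """
    records: list[ComplexRecord] = []
    for unit in antibody_units:
        complexed = False
        for antigen in antigen_units:
            n = count_cdr_contacts(unit, antigen, model, contact_cutoff)
            if n < 1:
                continue
            if antigen.n_residues(model) <= min_antigen_len:
                log.info("antigen %s in contact but too short; excluded "
                         "from the complex subset", "+".join(antigen.chain_ids))
                continue
            records.append(ComplexRecord(unit, antigen, n))
            complexed = True
        if not complexed:
            records.append(ComplexRecord(unit, None, 0))
    return records


# ---------------------------------------------------------------------------
# Renaming and file splitting

_FALLBACK_IDS = "ABCDEFGIJKMNOPQRSTUVWXYZ0123456789"


def antibody_chain_names(unit: AntibodyUnit) -> dict:
    """Target names for a unit's domains: H/L, single H or L, or h/l (scFv)."""
    if unit.format == "scfv":
        return {d.domain_type: "h" if d.domain_type == "VH" else "l"
                for d in unit.domains}
    return {d.domain_type: "H" if d.domain_type == "VH" else "L"
            for d in unit.domains}


def rename_antigen_chain(original: str, taken: set[str]) -> str:
    """Antigen chains keep their id unless it collides with antibody naming.

    Ids H or L (reserved for the antibody) become 'A'; if the preferred
    name is already taken a deterministic fallback is chosen and logged.
    """
    preferred = "A" if original in ("H", "L", "h", "l") else original
    if preferred not in taken:
        return preferred
    for cand in _FALLBACK_IDS:
        if cand not in taken:
            log.warning("chain id %r taken; antigen chain %r renamed to %r",
                        preferred, original, cand)
            return cand
    raise ValueError("no chain ids left")


def rename_chains(record: ComplexRecord, model: StructureModel
                  ) -> StructureModel:
    """Build the standardized output model for one record.

    Antibody chains are trimmed to their Martin-renumbered variable
    regions and renamed H/L (h/l for scFv halves); antigen chains keep
    their original ids except those named H or L, which become 'A'
    (deterministic fallback on collision).
    """
    out_chains: list[Chain] = []
    taken: set[str] = set()
    for dom in record.antibody.domains:
        src = model.chain(dom.chain_id)
        if src is None:
            raise KeyError(f"chain {dom.chain_id!r} missing from model")
        renum = renumber_to_martin(src, dom)
        name = antibody_chain_names(record.antibody)[dom.domain_type]
        out_chains.append(Chain(name, [r.copy() for r in renum.residues]))
        taken.add(name)
    if record.antigen is not None:
        for cid in record.antigen.chain_ids:
            src = model.chain(cid)
            if src is None:
                raise KeyError(f"antigen chain {cid!r} missing from model")
            new_id = rename_antigen_chain(cid, taken)
            taken.add(new_id)
            out_chains.append(Chain(new_id, [r.copy() for r in src.residues]))
    return StructureModel(model.entry_id, out_chains, model.metadata)


def split_and_name(records: Sequence[ComplexRecord], model: StructureModel
                   ) -> list[tuple[str, StructureModel]]:
    """One (``XXXX_n``, model) per record, n assigned deterministically.

    Records are ordered by antibody chain ids, then antigen chain ids;
    re-running on identical input yields identical names and order.
    """
    def key(rec: ComplexRecord) -> tuple:
        ag = tuple(rec.antigen.chain_ids) if rec.antigen else ()
        return (rec.antibody.sort_key, ag)

    ordered = sorted(records, key=key)
    out = []
    for i, rec in enumerate(ordered, start=1):
        rec.output_name = f"{model.entry_id}_{i}"
        out.append((rec.output_name, rename_chains(rec, model)))
    return out


# ---------------------------------------------------------------------------
# Dataset profiling

@dataclass
class DatasetProfile:
    """Experimental-method and resolution summary over a set of entries."""

    n_entries: int
    method_percent: dict[str, float]
    method_mean_resolution: dict[str, Optional[float]]
    fraction_below_cutoff: Optional[float]
    resolution_cutoff: float
    n_without_resolution: int = 0

    def as_dict(self) -> dict:
        return {
            "n_entries": self.n_entries,
            "method_percent": self.method_percent,
            "method_mean_resolution": self.method_mean_resolution,
            "fraction_below_cutoff": self.fraction_below_cutoff,
            "resolution_cutoff": self.resolution_cutoff,
            "n_without_resolution": self.n_without_resolution,
        }


def profile_dataset(metadata: Sequence[StructureMetadata],
                    resolution_cutoff: float = 4.0) -> DatasetProfile:
    """Per-method percentages and resolution statistics.

    Entries without a resolution are excluded from all resolution
    statistics and counted separately.
    """
    n = len(metadata)
    by_method: dict[str, list[Optional[float]]] = {}
    for m in metadata:
        by_method.setdefault(m.method, []).append(m.resolution)
    method_percent = {k: 100.0 * len(v) / n for k, v in by_method.items()} if n else {}
    method_mean: dict[str, Optional[float]] = {}
    for k, v in by_method.items():
        vals = [x for x in v if x is not None]
        method_mean[k] = float(np.mean(vals)) if vals else None
    with_res = [m.resolution for m in metadata if m.resolution is not None]
    frac = (float(np.mean([r < resolution_cutoff for r in with_res]))
            if with_res else None)
    return DatasetProfile(
        n_entries=n,
        method_percent=method_percent,
        method_mean_resolution=method_mean,
        fraction_below_cutoff=frac,
        resolution_cutoff=resolution_cutoff,
        n_without_resolution=n - len(with_res),
    )
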