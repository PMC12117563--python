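"""DockQ-style scoring of docked poses against a reference complex.

The three classical components are combined into one [0, 1] score:

* Fnat — fraction of the reference's interfacial residue contacts
  (any heavy-atom pair within 5 A) recovered by the pose;
* LRMS — ligand backbone RMSD after superposing on the receptor backbone;
* iRMS — backbone RMSD over the reference-defined interface residues
  (any heavy atom within 10 A of the other partner) after superposing on
  that interface;
* DockQ = (Fnat + 1/(1+(iRMS/1.5)^2) + 1/(1+(LRMS/8.5)^2)) / 3.

Poses are then binned into the four standard quality categories
(high >= 0.80, medium >= 0.49, acceptable >= 0.23, else incorrect).
The receptor is the antigen and the ligand the antibody throughout.
Residue correspondence between pose and reference is positional —
(chain, number, insertion code) after standardization — with no
alignment fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .geometry import kabsch
from .model import StructureModel, coords_of

__all__ = [
    "CONTACT_CUTOFF", "INTERFACE_CUTOFF", "BACKBONE_ATOMS",
    "D_IRMS", "D_LRMS", "THRESHOLDS",
    "DockScore", "native_contacts", "fnat", "superpose",
    "lrms", "irms", "dockq_score", "classify", "score_pose",
    "select_descriptor_poses",
]

CONTACT_CUTOFF = 5.0       # A, heavy-atom contact distance for Fnat
INTERFACE_CUTOFF = 10.0    # A, heavy-atom distance defining the interface
BACKBONE_ATOMS = ("N", "CA", "C", "O")
D_IRMS = 1.5               # A, iRMS scaling constant
D_LRMS = 8.5               # A, LRMS scaling constant
#: quality category lower bounds, descending
THRESHOLDS = (("high", 0.80), ("medium", 0.49), ("acceptable", 0.23))

ResKey = tuple[str, int, str]
ContactPair = tuple[ResKey, ResKey]


@dataclass(frozen=True)
class DockScore:
    """Component scores and quality category for one pose."""

    fnat: float
    irms: float
    lrms: float
    dockq: float
    category: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.fnat <= 1.0:
            raise ValueError("fnat must lie in [0, 1]")
        if self.irms < 0 or self.lrms < 0:
            raise ValueError("RMSDs must be non-negative")
        if not 0.0 <= self.dockq <= 1.0:
            raise ValueError("dockq must lie in [0, 1]")
        if self.category != classify(self.dockq):
            raise ValueError("category inconsistent with score")


def _residues_of(model: StructureModel, chain_ids: Sequence[str]):
    for cid in chain_ids:
        chain = model.chain(cid)
        if chain is None:
            raise KeyError(f"chain {cid!r} absent from {model.entry_id}")
        for res in chain:
            yield (cid, res.seq_number, res.insertion_code), res


def _heavy_coords(res) -> np.ndarray:
    pts = [a.coord for a in res.atoms if a.element != "H"]
    return np.vstack(pts) if pts else np.zeros((0, 3))


def residue_contacts(model: StructureModel, receptor_chains: Sequence[str],
                     ligand_chains: Sequence[str],
                     cutoff: float = CONTACT_CUTOFF) -> set[ContactPair]:
    """All (receptor residue, ligand residue) pairs with any heavy-atom
    pair closer than ``cutoff``."""
    rec = [(k, _heavy_coords(r)) for k, r in _residues_of(model, receptor_chains)]
    lig = [(k, _heavy_coords(r)) for k, r in _residues_of(model, ligand_chains)]
    out: set[ContactPair] = set()
    c2 = cutoff ** 2
    for rk, rc in rec:
        if len(rc) == 0:
            continue
        for lk, lc in lig:
            if len(lc) == 0:
                continue
            d2 = ((rc[:, None, :] - lc[None, :, :]) ** 2).sum(-1)
            if (d2 < c2).any():
                out.add((rk, lk))
    return out


def native_contacts(reference: StructureModel, receptor_chains: Sequence[str],
                    ligand_chains: Sequence[str],
                    cutoff: float = CONTACT_CUTOFF) -> set[ContactPair]:
    """Interfacial residue contacts of the reference complex.

    Raises if no contacts exist — the reference would not be a complex.
    """
    contacts = residue_contacts(reference, receptor_chains, ligand_chains, cutoff)
    if not contacts:
        raise ValueError("reference has no interfacial contacts at "
                         f"{cutoff} A; not a complex")
    return contacts


def fnat(pose: StructureModel, native: set[ContactPair],
         receptor_chains: Sequence[str], ligand_chains: Sequence[str],
         cutoff: float = CONTACT_CUTOFF) -> float:
    """Fraction of native contacts preserved in the pose."""
    pose_keys = {k for k, _ in _residues_of(pose, list(receptor_chains)
                                            + list(ligand_chains))}
    needed = {k for pair in native for k in pair}
    missing = needed - pose_keys
    if missing:
        raise ValueError(f"pose lacks residues of native contacts: "
                         f"{sorted(missing)[:5]}...")
    pose_contacts = residue_contacts(pose, receptor_chains, ligand_chains, cutoff)
    return len(pose_contacts & native) / len(native)


def superpose(mobile: np.ndarray, target: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (proper rotation only).

    Returns ``(R, t, rmsd)`` with ``mobile @ R.T + t`` fitted onto
    ``target``.  Degenerate input raises.
    """
    return kabsch(np.asarray(mobile, float), np.asarray(target, float))


def _paired_backbone(pose: StructureModel, reference: StructureModel,
                     keys: Sequence[ResKey]) -> tuple[np.ndarray, np.ndarray]:
    """Backbone coordinates over ``keys``, restricted to atoms present in
    both pose and reference, in matching order."""
    ref_res = dict(_residues_of(reference, sorted({k[0] for k in keys})))
    pose_res = dict(_residues_of(pose, sorted({k[0] for k in keys})))
    p, q = [], []
    for key in keys:
        r_ref = ref_res.get(key)
        r_pose = pose_res.get(key)
        if r_ref is None or r_pose is None:
            raise ValueError(f"residue {key} unmappable between pose and reference")
        for name in BACKBONE_ATOMS:
            a_ref = r_ref.atom(name)
            a_pose = r_pose.atom(name)
            if a_ref is not None and a_pose is not None:
                q.append(a_ref.coord)
                p.append(a_pose.coord)
    if not p:
        raise ValueError("no mappable backbone atoms")
    return np.vstack(p), np.vstack(q)


def lrms(pose: StructureModel, reference: StructureModel,
         receptor_chains: Sequence[str], ligand_chains: Sequence[str]) -> float:
    """Ligand backbone RMSD after superposing pose onto the reference
    receptor backbone."""
    rec_keys = [k for k, _ in _residues_of(reference, receptor_chains)]
    lig_keys = [k for k, _ in _residues_of(reference, ligand_chains)]
    p_rec, q_rec = _paired_backbone(pose, reference, rec_keys)
    R, t, _ = superpose(p_rec, q_rec)
    p_lig, q_lig = _paired_backbone(pose, reference, lig_keys)
    diff = p_lig @ R.T + t - q_lig
    return float(np.sqrt((diff ** 2).sum() / len(p_lig)))


def interface_residues(reference: StructureModel,
                       receptor_chains: Sequence[str],
                       ligand_chains: Sequence[str],
                       cutoff: float = INTERFACE_CUTOFF) -> list[ResKey]:
    """Reference residues of either partner with any heavy atom within
    ``cutoff`` of the other partner (defined on the reference only)."""
    pairs = residue_contacts(reference, receptor_chains, ligand_chains, cutoff)
    keys = {k for pair in pairs for k in pair}
    return sorted(keys)


def irms(pose: StructureModel, reference: StructureModel,
         receptor_chains: Sequence[str], ligand_chains: Sequence[str],
         interface_cutoff: float = INTERFACE_CUTOFF) -> float:
    """Backbone RMSD over the native interface after interface superposition."""
    keys = interface_residues(reference, receptor_chains, ligand_chains,
                              interface_cutoff)
    if not keys:
        raise ValueError("empty interface in reference")
    p, q = _paired_backbone(pose, reference, keys)
    _, _, rmsd = superpose(p, q)
    return rmsd


def dockq_score(fnat_value: float, lrms_value: float, irms_value: float) -> float:
    """Combine Fnat, LRMS and iRMS into the single quality score."""
    return (fnat_value
            + 1.0 / (1.0 + (irms_value / D_IRMS) ** 2)
            + 1.0 / (1.0 + (lrms_value / D_LRMS) ** 2)) / 3.0


def classify(score: float) -> str:
    """Quality category of a score, boundary-inclusive at each lower bound."""
    for name, bound in THRESHOLDS:
        if score >= bound:
            return name
    return "incorrect"


def score_pose(pose: StructureModel, reference: StructureModel,
               receptor_chains: Sequence[str], ligand_chains: Sequence[str],
               contact_cutoff: float = CONTACT_CUTOFF,
               interface_cutoff: float = INTERFACE_CUTOFF) -> DockScore:
    """Full DockQ evaluation of one pose against its reference."""
    native = native_contacts(reference, receptor_chains, ligand_chains,
                             contact_cutoff)
    f = fnat(pose, native, receptor_chains, ligand_chains, contact_cutoff)
    l = lrms(pose, reference, receptor_chains, ligand_chains)
    i = irms(pose, reference, receptor_chains, ligand_chains, interface_cutoff)
    q = dockq_score(f, l, i)
    return DockScore(fnat=f, irms=i, lrms=l, dockq=q, category=classify(q))


def select_descriptor_poses(scores: dict[str, DockScore],
                            n_select: int = 4) -> list[str]:
    """Pick the descriptor subset: one pose per represented quality category.

    The best-scoring pose of each represented category is taken (ties by
    pose id); missing categories are back-filled with additional incorrect
    poses in ascending score order, then, if incorrect poses run out, with
    the lowest-scoring remaining poses.  Requires at least ``n_select``
    poses.
    """
    if len(scores) < n_select:
        raise ValueError(f"need at least {n_select} poses, got {len(scores)}")
    by_cat: dict[str, list[str]] = {}
    for pid in sorted(scores):
        by_cat.setdefault(scores[pid].category, []).append(pid)
    chosen: list[str] = []
    for cat in ("high", "medium", "acceptable", "incorrect"):
        pids = by_cat.get(cat)
        if pids:
            best = sorted(pids, key=lambda p: (-scores[p].dockq, p))[0]
            chosen.append(best)
    remaining = [p for p in sorted(scores) if p not in chosen]
    # back-fill with incorrect poses, lowest scores first
    backfill = sorted((p for p in remaining
                       if scores[p].category == "incorrect"),
                      key=lambda p: (scores[p].dockq, p))
    for p in backfill:
        if len(chosen) >= n_select:
            break
        chosen.append(p)
    if len(chosen) < n_select:
        rest = sorted((p for p in remaining if p not in chosen),
                      key=lambda p: (scores[p].dockq, p))
        chosen.extend(rest[:n_select - len(chosen)])
    return chosen[:n_select]
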