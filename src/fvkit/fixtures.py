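"""Deterministic synthetic antibody-like structures for every pipeline stage.

Nothing here aims at physical realism: chains are laid out on simple
geometric paths with full heavy-atom residue templates (alphabet
restricted to Ala/Gly/Cys so completeness checks pass by construction).
What IS exact is the ground truth: conserved-cysteine Calpha separations,
CDR placements, contact counts, crystal-copy and oligomer topologies and
rigid pose transforms are all constructed to specification and returned
in machine-readable form, so tests never rely on hand-maintained files.

Martin numbering for the synthetic domains is carried by a
:class:`~fvkit.annotation.TableNumberingEngine` built alongside each
fixture, decoupling every downstream test from an external numbering
binary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .annotation import MartinPosition, TableNumberingEngine
from .geometry import build_backbone, rotation_matrix
from .model import Atom, Chain, Residue, StructureMetadata, StructureModel

__all__ = [
    "FixtureSpec", "DomainTruth", "FixtureResult",
    "make_fv", "make_complex", "make_pose", "make_ideal_secondary",
    "make_strand_pair", "line_chain",
]

_CA_SPACING = 3.8
_CONTACT_DZ = 7.0          # antigen head sits this far above its CDR partner
_COPY_SHIFT = 200.0        # separation between crystal copies
_PATCH_GAP = 5.2           # antigen-antigen Calpha gap in constructed patches

# Martin ranges of the synthetic domains (insertion-free by default)
_VH_MARTIN = list(range(25, 106))   # 81 residues; Cys at 92 -> index 67
_VL_MARTIN = list(range(20, 101))   # 81 residues; Cys at 88 -> index 68
_VH_CYS_IDX = _VH_MARTIN.index(92)
_VL_CYS_IDX = _VL_MARTIN.index(88)

_ONE_TO_THREE = {"A": "ALA", "G": "GLY", "C": "CYS"}

_COPY_CHAIN_IDS = ["BCD", "EFG", "IJK", "MNP", "QRS", "TUV"]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic antibody(-antigen) scene."""

    seed: int = 0
    n_fv: int = 1
    fv_separation: float = 15.0      # Cys92-Cys88 Calpha distance, A
    antigen_length: int = 60
    target_contacts: int = 5
    crystal_copies: int = 1
    oligomer: bool = False
    scfv: bool = False
    constant_tail: int = 0           # extra non-variable residues after VH/VL

    def __post_init__(self) -> None:
        for name in ("n_fv", "antigen_length", "target_contacts",
                     "crystal_copies", "constant_tail"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.fv_separation <= 0:
            raise ValueError("fv_separation must be positive")


@dataclass
class DomainTruth:
    """Ground truth for one synthetic variable domain."""

    chain_id: str
    domain_type: str
    sequence: str
    start_index: int                       # residue index of domain start in chain
    martin: list[MartinPosition]


@dataclass
class FixtureResult:
    """A synthetic model plus everything a test needs to verify it."""

    model: StructureModel
    engine: TableNumberingEngine
    domains: list[DomainTruth]
    antigen_chain_ids: list[str] = field(default_factory=list)
    cys_distances: dict = field(default_factory=dict)
    expected_contacts: dict = field(default_factory=dict)
    spec: Optional[FixtureSpec] = None


def _template_atoms(res_name: str, ca: np.ndarray, flip: bool = False) -> list[Atom]:
    """Full heavy-atom set for ALA/GLY/CYS around a given Calpha.

    ``flip`` rotates the template 180 degrees about the x-axis through the
    Calpha, pointing the side chain the other way (used to aim antigen
    side chains at the antibody so interfaces have heavy-atom contacts).
    """
    ca = np.asarray(ca, float)
    s = -1.0 if flip else 1.0

    def off(x: float, y: float, z: float) -> np.ndarray:
        return ca + (x, s * y, s * z)

    atoms = [
        Atom("N", "N", off(-1.20, -0.80, 0.35)),
        Atom("CA", "C", ca.copy()),
        Atom("C", "C", off(1.20, -0.80, -0.35)),
        Atom("O", "O", off(1.90, -1.75, -0.30)),
    ]
    if res_name != "GLY":
        atoms.append(Atom("CB", "C", off(0.05, 1.05, 1.10)))
        if res_name == "CYS":
            atoms.append(Atom("SG", "S", off(0.15, 2.00, 2.40)))
    return atoms


def line_chain(chain_id: str, sequence: str, origin: Sequence[float],
               direction: Sequence[float] = (1.0, 0.0, 0.0),
               spacing: float = _CA_SPACING, start_num: int = 1,
               ca_positions: Optional[np.ndarray] = None,
               flip_indices: frozenset = frozenset()) -> Chain:
    """Chain with Calpha atoms on a straight line (or explicit positions)."""
    origin = np.asarray(origin, float)
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    residues = []
    for i, one in enumerate(sequence):
        ca = (ca_positions[i] if ca_positions is not None
              else origin + i * spacing * direction)
        res_name = _ONE_TO_THREE.get(one, "ALA")
        residues.append(Residue(res_name, start_num + i, "",
                                _template_atoms(res_name, ca,
                                                flip=i in flip_indices)))
    return Chain(chain_id, residues)


def _domain_sequence(rng: np.random.Generator, length: int,
                     cys_index: int) -> str:
    seq = rng.choice(list("AG"), size=length)
    seq[cys_index] = "C"
    return "".join(seq)


def _register(engine: TableNumberingEngine, seq: str, dtype: str,
              martin_numbers: list[int]) -> list[MartinPosition]:
    positions: list[MartinPosition] = [(n, "") for n in martin_numbers]
    engine.register(seq, dtype, positions)
    return positions


def make_fv(spec: FixtureSpec) -> FixtureResult:
    """Paired VH/VL chains with exact conserved-cysteine separation.

    Each Fv copy is two parallel straight chains whose Martin-92 (VH) and
    Martin-88 (VL) Calpha atoms lie exactly ``spec.fv_separation`` apart.
    With ``spec.scfv`` both domains go on one chain joined by a linker;
    ``spec.constant_tail`` appends non-variable residues after each domain.
    """
    rng = np.random.default_rng(spec.seed)
    engine = TableNumberingEngine()
    vh_seq = _domain_sequence(rng, len(_VH_MARTIN), _VH_CYS_IDX)
    vl_seq = _domain_sequence(rng, len(_VL_MARTIN), _VL_CYS_IDX)
    vh_pos = _register(engine, vh_seq, "VH", _VH_MARTIN)
    vl_pos = _register(engine, vl_seq, "VL", _VL_MARTIN)
    tail = "".join(rng.choice(list("AG"), size=spec.constant_tail))

    chains: list[Chain] = []
    domains: list[DomainTruth] = []
    cys_distances: dict = {}
    n_copies = max(spec.n_fv, 1)
    for copy in range(n_copies):
        ids = _COPY_CHAIN_IDS[copy % len(_COPY_CHAIN_IDS)]
        z0 = copy * _COPY_SHIFT
        if spec.scfv:
            linker = "G" * 5
            seq = vh_seq + linker + vl_seq + tail
            n = len(seq)
            cas = np.zeros((n, 3))
            for i in range(len(vh_seq)):
                cas[i] = (i * _CA_SPACING, 0.0, z0)
            for i in range(len(vh_seq), len(vh_seq) + 5):
                cas[i] = ((i - len(vh_seq)) * _CA_SPACING, -30.0, z0)
            off = len(vh_seq) + 5
            for i in range(len(vl_seq) + spec.constant_tail):
                cas[off + i] = (-_CA_SPACING + i * _CA_SPACING,
                                -spec.fv_separation, z0)
            chain = line_chain(ids[0], seq, (0, 0, 0), ca_positions=cas)
            chains.append(chain)
            domains.append(DomainTruth(ids[0], "VH", vh_seq, 0, vh_pos))
            domains.append(DomainTruth(ids[0], "VL", vl_seq, off, vl_pos))
        else:
            vh_chain = line_chain(ids[0], vh_seq + tail, (0.0, 0.0, z0))
            # align VL so Cys88 shares the VH Cys92 x-coordinate
            vl_x0 = (_VH_CYS_IDX - _VL_CYS_IDX) * _CA_SPACING
            vl_chain = line_chain(ids[1], vl_seq + tail,
                                  (vl_x0, -spec.fv_separation, z0))
            chains.extend([vh_chain, vl_chain])
            domains.append(DomainTruth(ids[0], "VH", vh_seq, 0, vh_pos))
            domains.append(DomainTruth(ids[1], "VL", vl_seq, 0, vl_pos))
            cys_distances[(ids[0], ids[1])] = spec.fv_separation
    model = StructureModel("9FIX", chains,
                           StructureMetadata(method="xray", resolution=2.0))
    return FixtureResult(model, engine, domains,
                         cys_distances=cys_distances, spec=spec)


def _cdr_chain_indices(martin: list[int], spans) -> list[int]:
    return [i for i, num in enumerate(martin)
            if any(lo <= num <= hi for lo, hi in spans)]


def make_complex(spec: FixtureSpec) -> FixtureResult:
    """Fv copies plus antigen chains with an exact CDR contact count.

    Each copy's antigen "head" puts ``spec.target_contacts`` residues
    exactly 7.0 A above distinct VH CDR Calphas (one contact pair each at
    the 7.5 A counting cutoff); the remaining antigen residues form a
    remote tail.  With two crystal copies the second antigen's tail is
    placed against the first one — a couple of residues for a
    crystallographic-style patch, or the whole tail for a biological
    oligomer (``spec.oligomer``).
    """
    from .annotation import KABAT_STYLE_CDRS  # default CDR definition

    rng = np.random.default_rng(spec.seed)
    base = make_fv(FixtureSpec(seed=spec.seed, n_fv=spec.crystal_copies,
                               fv_separation=spec.fv_separation,
                               scfv=spec.scfv))
    cdr_idx = _cdr_chain_indices(_VH_MARTIN, KABAT_STYLE_CDRS.vh)
    k = spec.target_contacts
    if k > len(cdr_idx):
        raise ValueError(f"cannot place {k} contacts on {len(cdr_idx)} "
                         "CDR residues")
    if spec.antigen_length < k:
        raise ValueError("antigen shorter than the requested contact count")

    antigen_ids: list[str] = []
    chains = list(base.model.chains)
    n_copies = max(spec.crystal_copies, 1)
    tail_xs = None
    for copy in range(n_copies):
        ids = _COPY_CHAIN_IDS[copy % len(_COPY_CHAIN_IDS)]
        z0 = copy * _COPY_SHIFT
        seq = list(rng.choice(list("AG"), size=spec.antigen_length))
        # head residues are cysteines with the side chain aimed at the
        # antibody: each Calpha contact pair then also has a sub-5-A
        # heavy-atom contact, so the interface is real at both cutoffs
        for j in range(k):
            seq[j] = "C"
        seq = "".join(seq)
        n = len(seq)
        cas = np.zeros((n, 3))
        for j in range(k):
            x = cdr_idx[j] * _CA_SPACING
            cas[j] = (x, 0.0, z0 + _CONTACT_DZ)
        xs = []
        for j in range(k, n):
            x = (cdr_idx[k - 1] if k else 0) * _CA_SPACING + (j - k + 1) * _CA_SPACING
            cas[j] = (x, 0.0, z0 + 20.0)
            xs.append(x)
        if copy == 0:
            tail_xs = xs
        elif tail_xs is not None and xs:
            # pull tail residues of later copies next to the first tail
            n_patch = len(xs) if spec.oligomer else min(2, len(xs))
            for j in range(n_patch):
                cas[k + j] = (tail_xs[j] if j < len(tail_xs) else
                              tail_xs[-1] + _CA_SPACING * (j - len(tail_xs) + 1),
                              _PATCH_GAP, 20.0)
        chain = line_chain(ids[2], seq, (0, 0, 0), ca_positions=cas,
                           flip_indices=frozenset(range(k)))
        chains.append(chain)
        antigen_ids.append(ids[2])

    model = StructureModel("9FIX", chains, base.model.metadata)
    expected = {}
    for copy in range(n_copies):
        ids = _COPY_CHAIN_IDS[copy % len(_COPY_CHAIN_IDS)]
        expected[ids[0]] = k
    result = FixtureResult(model, base.engine, base.domains,
                           antigen_chain_ids=antigen_ids,
                           cys_distances=base.cys_distances,
                           expected_contacts=expected, spec=spec)
    _verify_contacts(result)
    return result


def _verify_contacts(result: FixtureResult) -> None:
    """Constructed geometry must reproduce the requested contact count."""
    from .annotation import detect_domains
    from .standardization import (build_antibody_units, count_cdr_contacts,
                                  AntigenUnit)

    domains = detect_domains(result.model, result.engine)
    units = build_antibody_units(domains, result.model)
    for unit in units:
        vh_chain = unit.chain_ids[0]
        want = result.expected_contacts.get(vh_chain)
        if want is None:
            continue
        got = sum(count_cdr_contacts(unit, AntigenUnit([aid]), result.model)
                  for aid in result.antigen_chain_ids)
        if got != want:
            raise ValueError(
                f"fixture geometry infeasible: wanted {want} contacts for "
                f"unit {unit.chain_ids}, built {got}")


def make_pose(reference: StructureModel, ligand_chains: Sequence[str],
              translation: Sequence[float] = (0.0, 0.0, 0.0),
              rotation_axis: Sequence[float] = (0.0, 0.0, 1.0),
              rotation_angle: float = 0.0
              ) -> tuple[StructureModel, tuple[np.ndarray, np.ndarray]]:
    """Rigidly perturb the ligand (antibody) chains of a complex.

    Rotation is about the ligand centroid, then the translation is
    applied; receptor chains are untouched.  Returns the pose and the
    exact ``(R, t)`` applied to ligand coordinates (``x' = R (x - c) + c
    + t`` with centroid ``c`` folded into ``t``).
    """
    pose = reference.copy()
    R = rotation_matrix(rotation_axis, rotation_angle)
    shift = np.asarray(translation, float)
    lig_atoms = [a for cid in ligand_chains for a in pose.chain(cid).atoms()]
    centroid = np.mean([a.coord for a in lig_atoms], axis=0)
    t = centroid - R @ centroid + shift
    for atom in lig_atoms:
        atom.coord = R @ atom.coord + t
    return pose, (R, t)


def make_ideal_secondary(kind: str, length: int, chain_id: str = "A") -> Chain:
    """A poly-Ala chain built from ideal internal coordinates.

    ``kind`` is ``helix`` (phi, psi = -57, -47) or ``strand``
    (-139, 135).  Interior residues of a helix satisfy the i -> i+4
    backbone hydrogen bonds that define the alpha conformation.
    """
    if length < 6:
        raise ValueError("need length >= 6")
    if kind == "helix":
        phi_psi = [(-57.0, -47.0)] * length
    elif kind == "strand":
        phi_psi = [(-139.0, 135.0)] * length
    else:
        raise ValueError(f"unknown kind {kind!r}")
    coords = build_backbone(phi_psi, with_cb=True)
    residues = []
    for i, atoms in enumerate(coords):
        alist = [Atom(name, name[0], xyz) for name, xyz in atoms.items()]
        residues.append(Residue("ALA", i + 1, "", alist))
    return Chain(chain_id, residues)


def make_strand_pair(length: int = 8, chain_id: str = "A") -> Chain:
    """Two antiparallel ideal strands on one chain, hydrogen-bond paired.

    The second strand is the first rotated 180 degrees and translated;
    the translation is chosen by a geometric grid search that puts
    inter-strand O..N distances at hydrogen-bond range (~2.9 A).  The
    numbering jumps between the strands, so there is a chain break.
    """
    strand = make_ideal_secondary("strand", length, chain_id)
    coords1 = [{a.name: a.coord for a in r.atoms} for r in strand.residues]
    axis_pt = np.mean([c["CA"] for c in coords1], axis=0)
    # an antiparallel sheet has a 2-fold axis perpendicular to the strand
    # direction in the sheet plane: rotate the copy 180 degrees about z
    R = rotation_matrix((0.0, 0.0, 1.0), 180.0)

    def placed(offset: np.ndarray) -> list[dict]:
        return [{n: R @ (c - axis_pt) + axis_pt + offset
                 for n, c in atoms.items()} for atoms in coords1]

    def h_dir(bbs: list[dict], i: int) -> Optional[np.ndarray]:
        if i == 0:
            return None
        u1 = bbs[i]["N"] - bbs[i - 1]["C"]
        u2 = bbs[i]["N"] - bbs[i]["CA"]
        u1 /= np.linalg.norm(u1)
        u2 /= np.linalg.norm(u2)
        d = u1 + u2
        return d / np.linalg.norm(d)

    def directed_bond(donor: list[dict], di: int,
                      acceptor: list[dict], ai: int) -> bool:
        v = acceptor[ai]["O"] - donor[di]["N"]
        d = np.linalg.norm(v)
        if not 2.8 <= d <= 3.1:
            return False
        h = h_dir(donor, di)
        return h is not None and np.dot(h, v) / d > 0.85

    def n_bonds(a: list[dict], b: list[dict]) -> int:
        return sum(directed_bond(a, i, b, j) + directed_bond(b, j, a, i)
                   for i in range(length) for j in range(length))

    best = None
    for dy in np.arange(3.8, 5.6, 0.1):
        for dx in np.arange(-6.0, 6.0, 0.1):
            offset = np.array([dx, dy, 0.0])
            c2 = placed(offset)
            good = n_bonds(coords1, c2)
            if best is None or good > best[0]:
                best = (good, offset)
    c2 = placed(best[1])
    residues = [r.copy() for r in strand.residues]
    for i, atoms in enumerate(c2):
        residues.append(Residue("ALA", 101 + i, "",
                                [Atom(n, n[0], xyz) for n, xyz in atoms.items()]))
    return Chain(chain_id, residues)
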