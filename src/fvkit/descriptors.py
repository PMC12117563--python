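"""Per-residue molecular descriptors and the CSV table emitter.

The suite covers surface exposure (Shrake-Rupley SASA, relative SASA),
burial (residue depth, half-sphere exposure), shape (protrusion index),
chemistry (hydrophobicity), and conformation (Calpha coordinates, phi/psi
torsions, 3-state secondary structure by Kabsch-Sander hydrogen bonds).
One residue yields exactly one row of the output table.

All estimators are deterministic for a fixed configuration: sphere points
come from a golden-spiral lattice, not random sampling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import dihedral, place_atom, IDEAL
from .model import Chain, Residue, ResidueId, StructureModel

__all__ = [
    "DescriptorConfig",
    "SasaResult",
    "sasa",
    "relative_sasa",
    "residue_depth",
    "protrusion_index",
    "half_sphere_exposure",
    "dihedrals",
    "secondary_structure",
    "hydrophobicity",
    "ResidueDescriptorRow",
    "compute_descriptors",
    "write_descriptor_table",
    "CSV_COLUMNS",
    "VDW_RADII",
    "MAX_ASA_TIEN",
    "KYTE_DOOLITTLE",
]

log = logging.getLogger(__name__)

ResKey = tuple[str, ResidueId]  # (chain_id, (seq_number, insertion_code))

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
             "P": 1.80, "SE": 1.90}
_DEFAULT_VDW = 1.70

#: Theoretical maximum accessible surface areas (A^2) per residue type
#: (Tien et al. 2013), the denominators of relative SASA.
MAX_ASA_TIEN = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}


@dataclass
class DescriptorConfig:
    """Tunable parameters of the descriptor suite.

    Defaults follow each descriptor's original publication: 1.4 A water
    probe with 960 Shrake-Rupley sphere points; protrusion-index sphere
    of 10 A with 20.1 A^3 mean atom volume, capped at 15; half-sphere
    exposure radius 13 A.
    """

    probe_radius: float = 1.4
    n_sphere_points: int = 960
    cx_radius: float = 10.0
    mean_atom_volume: float = 20.1
    cx_cap: float = 15.0
    hse_radius: float = 13.0
    chain_break_cutoff: float = 2.5
    max_asa: dict = field(default_factory=lambda: dict(MAX_ASA_TIEN))
    hydrophobicity_scale: dict = field(default_factory=lambda: dict(KYTE_DOOLITTLE))


def _sphere_points(n: int) -> np.ndarray:
    """n points quasi-uniform on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _atom_arrays(model: StructureModel) -> tuple[np.ndarray, np.ndarray, list[ResKey]]:
    coords, radii, keys = [], [], []
    for chain in model.chains:
        for res in chain:
            for atom in res.atoms:
                if atom.element == "H":
                    continue
                coords.append(atom.coord)
                radii.append(VDW_RADII.get(atom.element, _DEFAULT_VDW))
                keys.append((chain.chain_id, res.rid))
    if not coords:
        raise ValueError("structure has no heavy atoms")
    return np.vstack(coords), np.asarray(radii), keys


@dataclass
class SasaResult:
    """Per-atom and per-residue solvent-accessible surface areas.

    ``surface_dots`` are points on the van der Waals surface in solvent-
    accessible directions; they define the surface used by residue depth.
    """

    atom_areas: np.ndarray
    atom_keys: list[ResKey]
    residue_areas: dict[ResKey, float]
    surface_dots: np.ndarray

    def residue_area(self, chain_id: str, rid: ResidueId) -> float:
        return self.residue_areas.get((chain_id, rid), 0.0)


def sasa(model: StructureModel, probe_radius: float = 1.4,
         n_sphere_points: int = 960) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area.

    Test points are placed on each atom's expanded sphere (vdW + probe);
    a point is accessible when outside every other atom's expanded sphere.
    Per-residue area is the sum over the residue's heavy atoms.
    """
    coords, radii, keys = _atom_arrays(model)
    n = len(coords)
    expanded = radii + probe_radius
    unit = _sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()

    atom_areas = np.zeros(n)
    dots: list[np.ndarray] = []
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach)
                     if j != i]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= expanded[j]
        frac = accessible.mean()
        atom_areas[i] = frac * 4.0 * math.pi * expanded[i] ** 2
        if accessible.any():
            # depth surface: dots at the vdW radius in accessible directions
            dots.append(coords[i] + radii[i] * unit[accessible])
    residue_areas: dict[ResKey, float] = {}
    for area, key in zip(atom_areas, keys):
        residue_areas[key] = residue_areas.get(key, 0.0) + float(area)
    surface = np.vstack(dots) if dots else np.zeros((0, 3))
    return SasaResult(atom_areas, keys, residue_areas, surface)


def relative_sasa(residue_area: float, res_name: str,
                  max_asa: Optional[dict] = None) -> Optional[float]:
    """Residue SASA divided by its type's reference maximum.

    Unknown residue types yield None (logged), not an exception.
    """
    table = max_asa if max_asa is not None else MAX_ASA_TIEN
    ref = table.get(res_name)
    if ref is None:
        log.warning("no reference ASA for residue %r", res_name)
        return None
    return float(residue_area) / ref


def residue_depth(model: StructureModel, probe_radius: float = 1.4,
                  n_sphere_points: int = 960,
                  sasa_result: Optional[SasaResult] = None) -> dict[ResKey, float]:
    """Mean distance of each residue's heavy atoms to the accessible surface.

    The surface is the dot cloud of :func:`sasa`; exposed atoms sit within
    their own vdW radius of it, buried atoms farther.  A single-atom model
    has depth 0 by convention.
    """
    coords, _, keys = _atom_arrays(model)
    if len(coords) == 1:
        return {keys[0]: 0.0}
    res = sasa_result if sasa_result is not None else sasa(
        model, probe_radius, n_sphere_points)
    if len(res.surface_dots) == 0:
        # fully occluded everywhere (degenerate); report zeros
        return {k: 0.0 for k in set(keys)}
    tree = cKDTree(res.surface_dots)
    dist, _ = tree.query(coords)
    depths: dict[ResKey, list[float]] = {}
    for d, key in zip(dist, keys):
        depths.setdefault(key, []).append(float(d))
    return {k: float(np.mean(v)) for k, v in depths.items()}


def protrusion_index(model: StructureModel, sphere_radius: float = 10.0,
                     mean_atom_volume: float = 20.1,
                     cap: float = 15.0) -> dict[ResKey, float]:
    """Protrusion index (CX): free-to-occupied volume ratio per residue.

    For each heavy atom, the occupied volume inside a ``sphere_radius``
    sphere is the neighbor count (the atom itself included) times the mean
    atom volume; CX = V_free / V_occupied, capped.  Per-residue CX is the
    mean over the residue's atoms.
    """
    coords, _, keys = _atom_arrays(model)
    tree = cKDTree(coords)
    counts = np.array([len(tree.query_ball_point(c, sphere_radius))
                       for c in coords], dtype=float)
    v_sphere = 4.0 / 3.0 * math.pi * sphere_radius ** 3
    v_int = counts * mean_atom_volume
    cx = np.minimum((v_sphere - v_int) / v_int, cap)
    cx = np.maximum(cx, 0.0)
    per_res: dict[ResKey, list[float]] = {}
    for val, key in zip(cx, keys):
        per_res.setdefault(key, []).append(float(val))
    return {k: float(np.mean(v)) for k, v in per_res.items()}


def _pseudo_cb(res: Residue) -> Optional[np.ndarray]:
    cb = res.atom("CB")
    if cb is not None:
        return cb.coord
    n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
    if n is None or ca is None or c is None:
        return None
    return place_atom(c.coord, n.coord, ca.coord,
                      IDEAL["ca_cb"], IDEAL["ang_n_ca_cb"], 122.6)


def half_sphere_exposure(chain: Chain, radius: float = 13.0
                         ) -> dict[ResidueId, Optional[tuple[int, int]]]:
    """Half-sphere exposure: Calpha neighbor counts above/below the CB plane.

    Neighbors are other residues' Calpha atoms within ``radius``; the
    'up' half-space is the side of the Calpha->CB vector (a pseudo-CB is
    constructed from the backbone when CB is absent, e.g. glycine).
    Residues without a Calpha get None.
    """
    cas = [(r.rid, r.ca.coord if r.ca else None) for r in chain]
    out: dict[ResidueId, Optional[tuple[int, int]]] = {}
    for res in chain:
        ca = res.ca
        if ca is None:
            out[res.rid] = None
            continue
        direction = None
        cb = _pseudo_cb(res)
        if cb is not None:
            direction = cb - ca.coord
        up = down = 0
        for rid, other in cas:
            if rid == res.rid or other is None:
                continue
            v = other - ca.coord
            if np.linalg.norm(v) > radius:
                continue
            if direction is None or np.dot(direction, v) > 0:
                up += 1
            else:
                down += 1
        out[res.rid] = (up, down)
    return out


def _backbone(res: Residue) -> Optional[dict[str, np.ndarray]]:
    atoms = {}
    for name in ("N", "CA", "C"):
        a = res.atom(name)
        if a is None:
            return None
        atoms[name] = a.coord
    o = res.atom("O")
    if o is not None:
        atoms["O"] = o.coord
    return atoms


def _bonded(prev: Optional[dict], cur: Optional[dict], cutoff: float) -> bool:
    if prev is None or cur is None:
        return False
    return float(np.linalg.norm(cur["N"] - prev["C"])) <= cutoff


def dihedrals(chain: Chain, chain_break_cutoff: float = 2.5
              ) -> dict[ResidueId, tuple[Optional[float], Optional[float]]]:
    """Backbone phi/psi per residue, degrees, IUPAC sign convention.

    Angles are absent (None) at chain termini, across chain breaks
    (peptide C-N distance above ``chain_break_cutoff``), and wherever
    backbone atoms are missing.
    """
    bbs = [_backbone(r) for r in chain]
    out: dict[ResidueId, tuple[Optional[float], Optional[float]]] = {}
    for i, res in enumerate(chain):
        phi = psi = None
        cur = bbs[i]
        if cur is not None:
            if i > 0 and _bonded(bbs[i - 1], cur, chain_break_cutoff):
                phi = dihedral(bbs[i - 1]["C"], cur["N"], cur["CA"], cur["C"])
            if i + 1 < len(bbs) and _bonded(cur, bbs[i + 1], chain_break_cutoff):
                psi = dihedral(cur["N"], cur["CA"], cur["C"], bbs[i + 1]["N"])
        out[res.rid] = (phi, psi)
    return out


# ---------------------------------------------------------------------------
# Kabsch-Sander secondary structure (3-state)

_HB_Q = 0.084 * 332.0      # electrostatic prefactor, kcal/mol * A
_HB_CUTOFF = -0.5          # kcal/mol
_NH_BOND = 1.01            # amide N-H length, A


def _amide_h(prev: Optional[dict], cur: dict, res_name: str,
             cutoff: float) -> Optional[np.ndarray]:
    if res_name == "PRO":
        return None
    if not _bonded(prev, cur, cutoff):
        return None
    u1 = cur["N"] - prev["C"]
    u2 = cur["N"] - cur["CA"]
    u1 /= np.linalg.norm(u1)
    u2 /= np.linalg.norm(u2)
    d = u1 + u2
    nd = np.linalg.norm(d)
    if nd < 1e-9:
        return None
    return cur["N"] + _NH_BOND * d / nd


def _hbond_energy(donor_n: np.ndarray, donor_h: np.ndarray,
                  acc_c: np.ndarray, acc_o: np.ndarray) -> float:
    r_on = np.linalg.norm(acc_o - donor_n)
    r_ch = np.linalg.norm(acc_c - donor_h)
    r_oh = np.linalg.norm(acc_o - donor_h)
    r_cn = np.linalg.norm(acc_c - donor_n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9  # clash: treat as bonded, as Kabsch-Sander do
    return _HB_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def secondary_structure(chain: Chain, chain_break_cutoff: float = 2.5
                        ) -> dict[ResidueId, str]:
    """3-state secondary structure (H/E/C) by Kabsch-Sander hydrogen bonds.

    A backbone hydrogen bond exists when the Kabsch-Sander electrostatic
    energy is below -0.5 kcal/mol.  Alpha-helix (H) comes from runs of
    i->i+4 bonds, strand (E) from parallel/antiparallel bridge patterns;
    everything else, including residues with missing carbonyl oxygens
    (logged), is coil (C).
    """
    residues = list(chain)
    n = len(residues)
    bbs = [_backbone(r) for r in residues]
    for i, (r, bb) in enumerate(zip(residues, bbs)):
        if bb is not None and "O" not in bb:
            log.warning("residue %s%s lacks O; treated as coil",
                        r.res_name, r.seq_number)
    hs = [None] * n
    for i in range(1, n):
        if bbs[i] is not None:
            hs[i] = _amide_h(bbs[i - 1], bbs[i], residues[i].res_name,
                             chain_break_cutoff)

    def hbond(i: int, j: int) -> bool:
        """True when N-H of residue i donates to C=O of residue j."""
        if not (0 <= i < n and 0 <= j < n) or abs(i - j) < 2:
            return False
        if hs[i] is None or bbs[j] is None or "O" not in bbs[j]:
            return False
        e = _hbond_energy(bbs[i]["N"], hs[i], bbs[j]["C"], bbs[j]["O"])
        return e < _HB_CUTOFF

    ss = ["C"] * n
    # 4-turns; two consecutive turns make a minimal alpha-helix
    turn4 = [hbond(i + 4, i) for i in range(n)]
    for i in range(n - 1):
        if turn4[i] and turn4[i + 1]:
            for k in range(i + 1, min(i + 5, n)):
                ss[k] = "H"
    # bridges
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            parallel = ((hbond(i + 1, j) and hbond(j, i - 1))
                        or (hbond(j + 1, i) and hbond(i, j - 1)))
            antiparallel = ((hbond(i, j) and hbond(j, i))
                            or (hbond(i + 1, j - 1) and hbond(j + 1, i - 1)))
            if parallel or antiparallel:
                for k in (i, j):
                    if ss[k] != "H":
                        ss[k] = "E"
    return {r.rid: s for r, s in zip(residues, ss)}


def hydrophobicity(res_name: str, scale: Optional[dict] = None) -> Optional[float]:
    """Hydrophobicity of a residue type (default Kyte-Doolittle)."""
    table = scale if scale is not None else KYTE_DOOLITTLE
    val = table.get(res_name)
    if val is None:
        log.warning("no hydrophobicity value for residue %r", res_name)
    return val


# ---------------------------------------------------------------------------
# Assembled rows and CSV emission

CSV_COLUMNS = [
    "chain_id", "res_number", "insertion_code", "res_name",
    "rel_sasa", "depth", "protrusion", "hydrophobicity",
    "hse_up", "hse_down", "ca_x", "ca_y", "ca_z",
    "phi", "psi", "sec_struct",
]


@dataclass
class ResidueDescriptorRow:
    """One residue's descriptor vector, one CSV row."""

    chain_id: str
    res_number: int
    insertion_code: str
    res_name: str
    rel_sasa: Optional[float]
    depth: Optional[float]
    protrusion: Optional[float]
    hydrophobicity: Optional[float]
    hse_up: Optional[int]
    hse_down: Optional[int]
    ca_x: Optional[float]
    ca_y: Optional[float]
    ca_z: Optional[float]
    phi: Optional[float]
    psi: Optional[float]
    sec_struct: str


def compute_descriptors(model: StructureModel,
                        config: Optional[DescriptorConfig] = None,
                        isolate: Optional[list[str]] = None
                        ) -> list[ResidueDescriptorRow]:
    """Full descriptor suite for every residue of ``model``.

    By default residues are described in the context of the whole file
    (a complexed residue is partially buried by its partner); pass
    ``isolate`` to restrict the model to a chain subset first.
    """
    cfg = config or DescriptorConfig()
    if isolate is not None:
        model = model.subset(isolate)
    sr = sasa(model, cfg.probe_radius, cfg.n_sphere_points)
    depth = residue_depth(model, cfg.probe_radius, cfg.n_sphere_points,
                          sasa_result=sr)
    cx = protrusion_index(model, cfg.cx_radius, cfg.mean_atom_volume, cfg.cx_cap)
    rows: list[ResidueDescriptorRow] = []
    for chain in model.chains:
        hse = half_sphere_exposure(chain, cfg.hse_radius)
        tors = dihedrals(chain, cfg.chain_break_cutoff)
        ss = secondary_structure(chain, cfg.chain_break_cutoff)
        for res in chain:
            key = (chain.chain_id, res.rid)
            ca = res.ca
            h = hse.get(res.rid)
            phi, psi = tors.get(res.rid, (None, None))
            rows.append(ResidueDescriptorRow(
                chain_id=chain.chain_id,
                res_number=res.seq_number,
                insertion_code=res.insertion_code,
                res_name=res.res_name,
                rel_sasa=relative_sasa(sr.residue_areas.get(key, 0.0),
                                       res.res_name, cfg.max_asa),
                depth=depth.get(key),
                protrusion=cx.get(key),
                hydrophobicity=hydrophobicity(res.res_name,
                                              cfg.hydrophobicity_scale),
                hse_up=None if h is None else h[0],
                hse_down=None if h is None else h[1],
                ca_x=None if ca is None else float(ca.coord[0]),
                ca_y=None if ca is None else float(ca.coord[1]),
                ca_z=None if ca is None else float(ca.coord[2]),
                phi=phi,
                psi=psi,
                sec_struct=ss.get(res.rid, "C"),
            ))
    return rows


def write_descriptor_table(rows: list[ResidueDescriptorRow],
                           path: Union[str, Path]) -> None:
    """Write rows as CSV with the fixed column order; absent values empty."""
    df = pd.DataFrame([{c: getattr(r, c) for c in CSV_COLUMNS} for r in rows],
                      columns=CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.4f")
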