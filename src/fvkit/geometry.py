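"""Shared 3D geometry: torsions, rigid superposition, backbone building.

The backbone builder places N/CA/C/O/CB atoms from ideal internal
coordinates (NeRF chain extension), which is what the synthetic fixtures
use to make helices, strands and extended chains with exact dihedrals.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "dihedral",
    "place_atom",
    "kabsch",
    "rotation_matrix",
    "build_backbone",
    "IDEAL",
]

# Engh–Huber style ideal bond lengths (A) and angles (deg)
IDEAL = {
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.231, "ca_cb": 1.521,
    "ang_n_ca_c": 111.2, "ang_ca_c_n": 116.2, "ang_c_n_ca": 121.7,
    "ang_ca_c_o": 120.8, "ang_n_ca_cb": 110.4, "omega": 180.0,
}


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees (IUPAC convention)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF: place atom d with |cd|=bond, angle(b,c,d)=angle and
    torsion(a,b,c,d)=torsion (degrees)."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_matrix(axis: Sequence[float], angle_deg: float) -> np.ndarray:
    """Proper rotation about ``axis`` by ``angle_deg`` (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(R, t, rmsd)`` with proper rotation R (det +1) such that
    ``mobile @ R.T + t`` best fits ``target``.  Degenerate (collinear or
    coincident) point sets raise ``ValueError``.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate sets must share shape (n, 3)")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    # collinearity check: rank of the centered set
    if (np.linalg.matrix_rank(P0, tol=1e-8) < 2
            or np.linalg.matrix_rank(Q0, tol=1e-8) < 2):
        raise ValueError("degenerate (collinear) coordinates")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - pc @ R.T
    diff = P @ R.T + t - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / P.shape[0]))
    return R, t, rmsd


def build_backbone(phi_psi: Sequence[tuple[Optional[float], Optional[float]]],
                   with_cb: bool = True) -> list[dict[str, np.ndarray]]:
    """Build N/CA/C/O(/CB) coordinates for a chain of given (phi, psi).

    ``phi_psi[i]`` supplies the torsions flanking residue i; phi of the
    first and psi of the last residue are ignored (undefined).  Omega is
    fixed trans.  Returns one dict of atom coordinates per residue.
    """
    n = len(phi_psi)
    if n < 1:
        raise ValueError("need at least one residue")
    residues: list[dict[str, np.ndarray]] = []
    # seed first residue in a canonical frame
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([IDEAL["n_ca"], 0.0, 0.0])
    ang = math.radians(IDEAL["ang_n_ca_c"])
    C = CA + IDEAL["ca_c"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    residues.append({"N": N, "CA": CA, "C": C})
    for i in range(1, n):
        prev = residues[-1]
        psi_prev = phi_psi[i - 1][1]
        if psi_prev is None:
            psi_prev = 180.0
        N = place_atom(prev["N"], prev["CA"], prev["C"],
                       IDEAL["c_n"], IDEAL["ang_ca_c_n"], psi_prev)
        CA = place_atom(prev["CA"], prev["C"], N,
                        IDEAL["n_ca"], IDEAL["ang_c_n_ca"], IDEAL["omega"])
        phi = phi_psi[i][0]
        if phi is None:
            phi = 180.0
        C = place_atom(prev["C"], N, CA,
                       IDEAL["ca_c"], IDEAL["ang_n_ca_c"], phi)
        residues.append({"N": N, "CA": CA, "C": C})
    # carbonyl O: in the peptide plane, trans to the next N (psi + 180)
    for i, res in enumerate(residues):
        if i + 1 < n:
            nxt = residues[i + 1]["N"]
            res["O"] = place_atom(nxt, res["CA"], res["C"],
                                  IDEAL["c_o"], IDEAL["ang_ca_c_o"], 180.0)
        else:
            psi = phi_psi[i][1]
            if psi is None:
                psi = 180.0
            res["O"] = place_atom(res["N"], res["CA"], res["C"],
                                  IDEAL["c_o"], IDEAL["ang_ca_c_o"], psi + 180.0)
    if with_cb:
        for res in residues:
            res["CB"] = place_atom(res["C"], res["N"], res["CA"],
                                   IDEAL["ca_cb"], IDEAL["ang_n_ca_cb"], 122.6)
    return residues
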