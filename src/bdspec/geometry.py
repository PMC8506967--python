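"""Distances, torsions, and closed-form rigid-body superposition.

The superposition is the Kabsch solution: SVD of the weighted covariance of
two centered point sets, with the determinant sign corrected so the result
is always a proper rotation (no reflections). Dihedrals follow the IUPAC
convention (cis = 0 deg, range (-180, 180]).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import GeometryError, SuperpositionError
from .structure_io import Residue

#: Heavy atom defining chi-1 (N-CA-CB-X) per residue type; default CG.
_CHI1_GAMMA = {
    "SER": "OG",
    "THR": "OG1",
    "CYS": "SG",
    "VAL": "CG1",
    "ILE": "CG1",
}
_NO_CHI1 = {"GLY", "ALA"}


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation matrix is not proper (det != +1)")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthogonal")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        out = pts @ self.rotation.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, IUPAC sign, range (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b2) < 1e-9:
        raise GeometryError("undefined dihedral: central atoms coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GeometryError("undefined dihedral: three collinear points")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m1 @ n2
    # sign flipped so that the result follows the IUPAC convention
    # (clockwise rotation of the far bond, viewed p2 -> p3, is positive)
    angle = np.degrees(np.arctan2(-y, x))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def chi1(residue: Residue, altloc: Optional[str] = None) -> float:
    """Sidechain chi-1 torsion N-CA-CB-gamma in degrees.

    For residues with alternate sidechain conformations pass the altloc id;
    atoms with a blank altloc (shared backbone) are always usable.
    """
    if residue.res_name.upper() in _NO_CHI1:
        raise GeometryError(f"{residue.label}: chi-1 undefined for {residue.res_name}")
    gamma_name = _CHI1_GAMMA.get(residue.res_name.upper(), "CG")
    coords = []
    for name in ("N", "CA", "CB", gamma_name):
        hits = residue.get_atoms(name, altloc=altloc)
        if not hits:
            raise GeometryError(
                f"{residue.label}: chi-1 undefined, missing atom {name}"
                + (f" (altloc {altloc})" if altloc else "")
            )
        # prefer the requested altloc over a blank-altloc fallback
        hits.sort(key=lambda a: a.altloc != (altloc or ""))
        coords.append(hits[0].pos)
    return dihedral(*coords)


def chi1_conformers(residue: Residue) -> dict[str, float]:
    """chi-1 per alternate conformation ('' key when no altlocs present)."""
    alts = residue.altlocs() or [""]
    return {alt: chi1(residue, altloc=alt or None) for alt in alts}


def kabsch(
    points_p: np.ndarray,
    points_q: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit mapping P onto Q; returns (transform, rmsd).

    Reflections are excluded by flipping the sign of the smallest singular
    vector when det < 0. With weights, both the centroids and the rmsd are
    weighted.
    """
    P = np.asarray(points_p, float)
    Q = np.asarray(points_q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise SuperpositionError("point sets must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise SuperpositionError(f"need >= 3 points, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise SuperpositionError("weights must be non-negative with positive sum")
    w = w / w.sum()
    cp = w @ P
    cq = w @ Q
    Pc = P - cp
    Qc = Q - cq
    H = (Pc * w[:, None]).T @ Qc
    if np.linalg.matrix_rank(H, tol=1e-10) < 2:
        raise SuperpositionError("degenerate (collinear or coincident) point sets")
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    transform = RigidTransform(R, t)
    dev = transform.apply(P) - Q
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", dev, dev))))
    return transform, rmsd


def min_heavy_atom_distance(
    residue_a: Residue, residue_b: Residue
) -> tuple[float, tuple[str, str]]:
    """Minimum heavy-atom distance over all altloc combinations.

    Ties are broken by (atom name of a, atom name of b) so results are
    deterministic regardless of file atom order.
    """
    heavy_a = residue_a.heavy_atoms()
    heavy_b = residue_b.heavy_atoms()
    if not heavy_a or not heavy_b:
        raise GeometryError("residue without heavy atoms in distance computation")
    pa = np.array([a.pos for a in heavy_a])
    pb = np.array([b.pos for b in heavy_b])
    d = cdist(pa, pb)
    dmin = d.min()
    pairs = [
        (heavy_a[i].name, heavy_b[j].name)
        for i, j in zip(*np.nonzero(np.isclose(d, dmin, rtol=0, atol=1e-12)))
    ]
    return float(dmin), min(pairs)


def pairwise_min_distance(
    residues_a: Sequence[Residue], residues_b: Sequence[Residue]
) -> np.ndarray:
    """Matrix of residue-residue minimum heavy-atom distances."""
    out = np.empty((len(residues_a), len(residues_b)))
    for i, ra in enumerate(residues_a):
        for j, rb in enumerate(residues_b):
            out[i, j] = min_heavy_atom_distance(ra, rb)[0]
    return out
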