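"""Rigid-body superposition, RMSD and backbone geometry.

Numerical core for comparing calcium-binding loop fragments: Kabsch
(least-squares) superposition of labelled point sets, construction of a
virtual C-beta from backbone N/CA/C (needed for Gly when measuring RMSD over
"extended main chain" atoms), and elementary internal coordinates (distances,
dihedrals, phi/psi).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

# Ideal internal coordinates for the constructed C-beta (standard
# L-amino-acid geometry): CA-CB bond length and the N-CA-CB / C-CA-CB angles.
CBETA_BOND_LENGTH = 1.522  # Angstrom
CBETA_ANGLE_N = 110.4  # degrees, N-CA-CB
CBETA_ANGLE_C = 110.6  # degrees, C-CA-CB

#: Atom names of the extended-main-chain set, per residue.
EXTENDED_MAINCHAIN_ATOMS = ("N", "CA", "C", "O", "CB")


class GeometryError(ValueError):
    """Degenerate or mismatched geometry input."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        tr = np.asarray(self.translation, dtype=float)
        if rot.shape != (3, 3) or tr.shape != (3,):
            raise GeometryError("rotation must be 3x3 and translation length 3")
        if abs(np.linalg.det(rot) - 1.0) > 1e-6:
            raise GeometryError("rotation matrix must be proper (det = +1)")
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-6):
            raise GeometryError("rotation matrix must be orthogonal")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def to_json_dict(self) -> dict:
        return {
            "rotation": [list(map(float, row)) for row in self.rotation],
            "translation": list(map(float, self.translation)),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["rotation"], float), np.array(d["translation"], float))


@dataclass
class PointSet:
    """Ordered, labelled 3-D point set used for superposition."""

    labels: list[str]
    coords: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise GeometryError("coords must be an N x 3 array")
        if len(self.labels) != len(self.coords):
            raise GeometryError("labels and coords must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise GeometryError("labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)


def _check_superposable(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise GeometryError(
            f"point sets differ in size: {a.shape[0]} vs {b.shape[0]}"
        )
    if a.shape[0] < 3:
        raise GeometryError("superposition requires at least 3 points")
    for name, pts in (("mobile", a), ("target", b)):
        centred = pts - pts.mean(axis=0)
        # rank < 2 means all points lie on one line (or a single point)
        if np.linalg.matrix_rank(centred, tol=1e-8) < 2:
            raise GeometryError(f"degenerate geometry: {name} points are collinear")


def kabsch_superpose(
    mobile: PointSet | np.ndarray, target: PointSet | np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the optimal proper rigid transform (reflections excluded) and the
    RMSD, in Angstrom, of the transformed mobile points against the target.
    """
    a = mobile.coords if isinstance(mobile, PointSet) else np.asarray(mobile, float)
    b = target.coords if isinstance(target, PointSet) else np.asarray(target, float)
    _check_superposable(a, b)

    a_mean = a.mean(axis=0)
    b_mean = b.mean(axis=0)
    # align_vectors solves the orthogonal Procrustes problem with the
    # reflection branch corrected (Kabsch); rssd is sqrt of the residual SSD.
    rot, rssd = Rotation.align_vectors(b - b_mean, a - a_mean)
    rmsd = float(rssd) / math.sqrt(a.shape[0])
    matrix = rot.as_matrix()
    transform = RigidTransform(matrix, b_mean - matrix @ a_mean)
    return transform, rmsd


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without superposition."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise GeometryError("point sets differ in size")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superposed_rmsd(
    mobile: PointSet | np.ndarray, target: PointSet | np.ndarray
) -> float:
    """RMSD after optimal rigid superposition."""
    return kabsch_superpose(mobile, target)[1]


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Construct an idealized C-beta position from backbone N, CA and C.

    The point is placed 1.522 A from CA with N-CA-CB = 110.4 deg and
    C-CA-CB = 110.6 deg, on the side corresponding to an L-amino acid.
    Used for Gly (which has no C-beta) in extended-main-chain comparisons.
    """
    n = np.asarray(n, float)
    ca = np.asarray(ca, float)
    c = np.asarray(c, float)
    u = n - ca
    v = c - ca
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        raise GeometryError("virtual_cbeta: coincident input points")
    u /= nu
    v /= nv
    w = np.cross(u, v)
    nw = np.linalg.norm(w)
    if nw < 1e-6:
        raise GeometryError("virtual_cbeta: collinear N, CA, C")
    w /= nw

    # Solve d = alpha*u + beta*v + gamma*w with d.u and d.v fixed by the
    # ideal angles and |d| = 1; gamma > 0 picks the L-configuration side
    # (positive improper dihedral CB-CA-N-C).
    cos_un = math.cos(math.radians(CBETA_ANGLE_N))
    cos_uc = math.cos(math.radians(CBETA_ANGLE_C))
    dot_uv = float(np.dot(u, v))
    denom = 1.0 - dot_uv**2
    alpha = (cos_un - cos_uc * dot_uv) / denom
    beta = (cos_uc - cos_un * dot_uv) / denom
    planar = alpha * u + beta * v
    gamma_sq = 1.0 - float(np.dot(planar, planar))
    if gamma_sq < 0.0:
        raise GeometryError("virtual_cbeta: near-collinear N, CA, C")
    direction = planar + math.sqrt(gamma_sq) * w
    return ca + CBETA_BOND_LENGTH * direction


def distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance in Angstrom."""
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Bond angle a-b-c in degrees."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def dihedral(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray
) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def phi_psi(
    backbone: Sequence[dict[str, np.ndarray]],
) -> list[tuple[float | None, float | None]]:
    """Backbone phi/psi per residue.

    ``backbone`` is a sequence of per-residue dicts with keys "N", "CA", "C".
    phi is undefined (None) for the first residue, psi for the last.
    """
    out: list[tuple[float | None, float | None]] = []
    for i, res in enumerate(backbone):
        phi: float | None = None
        psi: float | None = None
        if i > 0:
            prev = backbone[i - 1]
            phi = dihedral(prev["C"], res["N"], res["CA"], res["C"])
        if i < len(backbone) - 1:
            nxt = backbone[i + 1]
            psi = dihedral(res["N"], res["CA"], res["C"], nxt["N"])
        out.append((phi, psi))
    return out
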