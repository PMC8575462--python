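"""Rigid-body and internal-coordinate geometry primitives.

Everything downstream (fragment dihedrals, synthetic peptide building,
pair-fit superposition) is built on the four primitives here: angle
wrapping on the circle, torsion measurement, NeRF-style atom placement
from internal coordinates, and least-squares rigid superposition with a
proper-rotation (no reflection) constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "superpose",
    "wrap_angle",
    "circular_difference",
    "dihedral",
    "bond_angle",
    "place_atom",
]


def wrap_angle(deg: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle in degrees into the half-open interval (-180, 180]."""
    wrapped = np.asarray(deg) % 360.0
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    if np.ndim(deg) == 0:
        return float(wrapped)
    return wrapped


def circular_difference(a, b):
    """Absolute circular distance between two angles in degrees, in [0, 180]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    d = np.where(d > 180.0, 360.0 - d, d)
    if np.ndim(a) == 0 and np.ndim(b) == 0:
        return float(d)
    return d


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention, (-180, 180]."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    norm1 = np.linalg.norm(n1)
    norm2 = np.linalg.norm(n2)
    if norm1 < 1e-12 or norm2 < 1e-12:
        return float("nan")  # colinear: torsion undefined
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = np.degrees(np.arctan2(y, x))
    return wrap_angle(ang)


def bond_angle(p0, p1, p2) -> float:
    """Angle p0-p1-p2 in degrees."""
    v1 = np.asarray(p0, float) - np.asarray(p1, float)
    v2 = np.asarray(p2, float) - np.asarray(p1, float)
    c = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(a, b, c, bond_length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom ``d`` bonded to ``c`` from internal coordinates (NeRF).

    The new atom satisfies |d-c| = bond_length, angle(b,c,d) = angle_deg and
    torsion(a,b,c,d) = torsion_deg.
    """
    if bond_length <= 0:
        raise ValueError("bond length must be positive")
    if not (0.0 < angle_deg < 180.0):
        raise ValueError("bond angle must lie strictly between 0 and 180 degrees")
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    d_local = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), -np.sin(theta) * np.sin(chi)]
    )
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc_hat)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-12:
        raise ValueError("reference atoms are colinear; torsion frame undefined")
    n_hat = n / n_norm
    m_hat = np.cross(n_hat, bc_hat)
    frame = np.column_stack([bc_hat, m_hat, n_hat])
    return c + frame @ d_local


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation + translation, no reflection)."""

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, float).reshape(3, 3)
        t = np.asarray(self.translation, float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("reflection is not a rigid motion")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of paired points (Kabsch algorithm).

    Returns the proper rigid transform minimizing sum ||R m_i + t - t_i||^2
    together with the residual RMSD. Reflections are rejected: for
    mirror-image point sets the best proper rotation is returned, with a
    non-zero RMSD.

    Colinear (or fewer than 3) point pairs leave a rotation about the common
    axis unresolved; fewer than 3 pairs is an error, exact colinearity is
    permitted but the returned transform is one minimizer among many.
    """
    mob = np.asarray(mobile, float)
    tgt = np.asarray(target, float)
    if mob.shape != tgt.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and target must be matching (n, 3) arrays")
    if mob.shape[0] < 3:
        raise ValueError("at least 3 point pairs are required")
    mc = mob.mean(axis=0)
    tc = tgt.mean(axis=0)
    H = (mob - mc).T @ (tgt - tc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    tform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((tform.apply(mob) - tgt) ** 2, axis=1))))
    return tform, rmsd
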