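"""Exact geometric kernel: measurements, internal<->Cartesian conversion, superposition.

All angles are in degrees at the API surface; distances in Angstrom. Dihedrals
follow the IUPAC sign convention (right-handed: looking down the b->c bond, the
far substituent clockwise of the near one gives a positive angle), returned in
(-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InternalCoordinate",
    "RigidTransform",
    "measure",
    "distance",
    "angle",
    "dihedral",
    "internal_to_cartesian",
    "ic_from_points",
    "superpose",
    "rmsd_no_fit",
    "wrap_degrees",
]

_EPS = 1e-10


class DegenerateGeometryError(ValueError):
    """Raised when a measurement or placement is geometrically undefined."""


@dataclass(frozen=True)
class InternalCoordinate:
    """Bond length (A), bond angle (deg, open interval (0,180)), torsion (deg]."""

    bond_length: float
    bond_angle: float
    torsion: float

    def __post_init__(self):
        if not self.bond_length > 0:
            raise ValueError(f"bond_length must be > 0, got {self.bond_length}")
        if not (0.0 < self.bond_angle < 180.0):
            raise DegenerateGeometryError(
                f"bond_angle must lie in (0, 180) deg, got {self.bond_angle}"
            )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ np.asarray(self.rotation).T + np.asarray(self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def wrap_degrees(x):
    """Wrap angle(s) to the interval (-180, 180]."""
    w = np.asarray(x, dtype=float)
    w = -((-w + 180.0) % 360.0 - 180.0)
    return float(w) if np.isscalar(x) or w.ndim == 0 else w


def distance(p: np.ndarray, q: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(p, float) - np.asarray(q, float)))


def angle(a, b, c) -> float:
    """Angle a-b-c in degrees, in [0, 180]."""
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    u, v = a - b, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _EPS or nv < _EPS:
        raise DegenerateGeometryError("coincident points in angle measurement")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(a, b, c, d) -> float:
    """Dihedral a-b-c-d in degrees, in (-180, 180], IUPAC sign convention."""
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < _EPS:
        raise DegenerateGeometryError("coincident central atoms in dihedral")
    if np.linalg.norm(n1) < _EPS or np.linalg.norm(n2) < _EPS:
        raise DegenerateGeometryError("collinear triple in dihedral measurement")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / nb2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return wrap_degrees(ang)


def measure(kind: str, points) -> float:
    """Measure a distance (2 points), angle (3) or dihedral (4 points)."""
    pts = [np.asarray(p, float) for p in points]
    if kind == "distance":
        if len(pts) != 2:
            raise ValueError("distance needs 2 points")
        return distance(*pts)
    if kind == "angle":
        if len(pts) != 3:
            raise ValueError("angle needs 3 points")
        return angle(*pts)
    if kind in ("dihedral", "improper_dihedral"):
        if len(pts) != 4:
            raise ValueError("dihedral needs 4 points")
        return dihedral(*pts)
    raise ValueError(f"unknown measurement kind: {kind}")


def internal_to_cartesian(a, b, c, ic: InternalCoordinate) -> np.ndarray:
    """Place atom d from frame atoms a, b, c (NeRF placement).

    The returned point satisfies |d-c| = bond_length, angle(b,c,d) = bond_angle
    and dihedral(a,b,c,d) = torsion, each to ~1e-9.
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    bc = c - b
    nbc = np.linalg.norm(bc)
    if nbc < _EPS:
        raise DegenerateGeometryError("frame atoms b and c coincide")
    bc /= nbc
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < _EPS:
        raise DegenerateGeometryError("frame atoms a, b, c are collinear")
    n /= nn
    m = np.cross(n, bc)
    theta = np.radians(ic.bond_angle)
    phi = np.radians(ic.torsion)
    r = ic.bond_length
    d2 = np.array(
        [
            -r * np.cos(theta),
            r * np.sin(theta) * np.cos(phi),
            r * np.sin(theta) * np.sin(phi),
        ]
    )
    M = np.column_stack([bc, m, n])
    return c + M @ d2


def ic_from_points(a, b, c, d) -> InternalCoordinate:
    """Inverse of :func:`internal_to_cartesian` on reference coordinates."""
    return InternalCoordinate(
        bond_length=distance(c, d), bond_angle=angle(b, c, d), torsion=dihedral(a, b, c, d)
    )


def rmsd_no_fit(a: np.ndarray, b: np.ndarray) -> float:
    """Direct coordinate RMSD without superposition (common-frame comparison)."""
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    if a.shape != b.shape:
        raise ValueError(f"coordinate sets differ in shape: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[float, RigidTransform]:
    """Kabsch least-squares superposition of mobile onto target.

    Correspondence is by row order. Returns the minimal RMSD and the proper
    rigid transform achieving it.
    """
    P = np.atleast_2d(np.asarray(mobile, float))
    Q = np.atleast_2d(np.asarray(target, float))
    if P.shape != Q.shape:
        raise ValueError(f"coordinate sets differ in shape: {P.shape} vs {Q.shape}")
    if P.shape[0] == 0:
        raise ValueError("empty coordinate sets")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    rmsd = rmsd_no_fit(moved, Q)
    return rmsd, RigidTransform(R, t)
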