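"""Torsion-space kinematic chains with batched forward kinematics.

A chain places atoms one NeRF step at a time from three previously available
atoms (fixed scaffold/partner atoms or earlier placed atoms).  Bond lengths
and bond angles are immutable; only torsions vary.  Each torsion is fixed or
driven by a variable (``torsion = sign * x[var] + offset``); variables are
free (periodic, sampled on a grid) or bounded (constraint tolerances).

Forward kinematics is vectorized over a batch of torsion vectors, and
analytic derivatives are available whenever each variable's influence is a
rigid rotation of its dependent atoms about its bond axis (verified at build
time; chains failing the check fall back to finite differences).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["TorsionVar", "ChainStep", "KinematicChain"]

_D2R = np.pi / 180.0


@dataclass
class TorsionVar:
    name: str
    lower: Optional[float] = None  # None = free (periodic)
    upper: Optional[float] = None
    seed: float = 180.0
    grid_kind: str = "sp3"  # "sp3" -> 120 deg grid, "sp2" -> 180 deg grid

    @property
    def bounded(self) -> bool:
        return self.lower is not None

    def grid(self, step_sp3: float = 120.0, step_sp2: float = 180.0) -> np.ndarray:
        """Start values for multistart sampling: bounded variables are seeded
        at their optimum; free torsions enumerate a staggered grid (default
        -60/60/180 for sp3, 0/180 for sp2-like)."""
        if self.bounded:
            return np.array([self.seed])
        step = step_sp3 if self.grid_kind == "sp3" else step_sp2
        n = max(1, int(round(360.0 / step)))
        start = -60.0 if self.grid_kind == "sp3" else 0.0
        return np.array([float(wrap(start + step * i)) for i in range(n)])


def wrap(x):
    return -((-np.asarray(x, float) + 180.0) % 360.0 - 180.0)


@dataclass
class ChainStep:
    name: str
    frame: tuple[int, int, int]  # indices into the combined atom array
    length: float
    angle: float
    torsion_offset: float = 0.0
    var_index: int = -1  # -1 = fixed torsion
    var_sign: float = 1.0


@dataclass
class KinematicChain:
    """Fixed seed atoms plus NeRF steps; atom i of the combined array is
    fixed_coords[i] for i < n_fixed, else the result of steps[i - n_fixed]."""

    fixed_coords: np.ndarray  # (F, 3)
    steps: list[ChainStep]
    variables: list[TorsionVar]
    atom_names: list[str] = field(default_factory=list)  # names of placed atoms
    groups: dict[str, list[int]] = field(default_factory=dict)  # placed-atom groups

    def __post_init__(self):
        self.fixed_coords = np.atleast_2d(np.asarray(self.fixed_coords, float))
        self.n_fixed = len(self.fixed_coords)
        self.n_placed = len(self.steps)
        self._analyze()

    # -- bookkeeping -------------------------------------------------------

    def index_of(self, name: str) -> int:
        return self.atom_names.index(name) + self.n_fixed

    @property
    def n_var(self) -> int:
        return len(self.variables)

    def seeds(self) -> np.ndarray:
        return np.array([v.seed for v in self.variables])

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([-np.inf if v.lower is None else v.lower for v in self.variables])
        hi = np.array([np.inf if v.upper is None else v.upper for v in self.variables])
        return lo, hi

    def _analyze(self):
        """Dependency analysis: per-variable affected sets, axes and whether the
        analytic rigid-rotation derivative is exact for this chain."""
        F, P = self.n_fixed, self.n_placed
        children: list[list[int]] = [[] for _ in range(F + P)]
        for i, st in enumerate(self.steps):
            for f in st.frame:
                children[f].append(F + i)
        var_steps: list[list[int]] = [[] for _ in self.variables]
        for i, st in enumerate(self.steps):
            if st.var_index >= 0:
                var_steps[st.var_index].append(i)
        self._var_axis: list[tuple[int, int]] = []
        self._var_affected: list[np.ndarray] = []
        self.analytic_ok = True
        for v, steps_v in enumerate(var_steps):
            if not steps_v:
                self._var_axis.append((0, 0))
                self._var_affected.append(np.zeros(0, dtype=int))
                continue
            axes = {(self.steps[i].frame[1], self.steps[i].frame[2]) for i in steps_v}
            signs = {self.steps[i].var_sign for i in steps_v}
            if len(axes) != 1 or len(signs) != 1:
                raise ValueError(
                    f"variable {self.variables[v].name} drives steps with different axes"
                )
            axis = next(iter(axes))
            own = {F + i for i in steps_v}
            affected: set[int] = set()
            stack = [F + i for i in steps_v]
            while stack:
                k = stack.pop()
                if k in affected:
                    continue
                affected.add(k)
                stack.extend(children[k])
            # Atoms placed directly by this variable's steps rotate rigidly by
            # definition (the variable IS their torsion about the axis); for
            # deeper descendants every frame atom must itself move rigidly.
            for k in affected - own:
                st = self.steps[k - F]
                for f in st.frame:
                    if f not in affected and f != axis[0] and f != axis[1]:
                        self.analytic_ok = False
            self._var_axis.append(axis)
            self._var_affected.append(np.array(sorted(affected), dtype=int))

    # -- forward kinematics ------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Place all atoms for torsion vectors ``x`` of shape (V,) or (S, V).

        Returns (S, F+P, 3) coordinates (S=1 collapses to (F+P, 3) when the
        input was one-dimensional).
        """
        x = np.asarray(x, float)
        single = x.ndim == 1
        X = x[None, :] if single else x
        S = X.shape[0]
        coords = np.empty((S, self.n_fixed + self.n_placed, 3))
        coords[:, : self.n_fixed] = self.fixed_coords[None]
        for i, st in enumerate(self.steps):
            a = coords[:, st.frame[0]]
            b = coords[:, st.frame[1]]
            c = coords[:, st.frame[2]]
            if st.var_index >= 0:
                tor = st.var_sign * X[:, st.var_index] + st.torsion_offset
            else:
                tor = np.full(S, st.torsion_offset)
            coords[:, self.n_fixed + i] = _nerf_batch(a, b, c, st.length, st.angle, tor)
        return coords[0] if single else coords

    def jacobian(self, x: np.ndarray, coords: Optional[np.ndarray] = None) -> np.ndarray:
        """d coords / d x (degrees) with shape (S, F+P, 3, V)."""
        x = np.atleast_2d(np.asarray(x, float))
        if coords is None:
            coords = self.forward(x)
        coords = np.atleast_3d(coords)
        if coords.ndim == 2:
            coords = coords[None]
        S, N, _ = coords.shape
        V = self.n_var
        if not self.analytic_ok:
            return self._jacobian_fd(x)
        J = np.zeros((S, N, 3, V))
        for v in range(V):
            aff = self._var_affected[v]
            if aff.size == 0:
                continue
            ib, ic = self._var_axis[v]
            axis = coords[:, ic] - coords[:, ib]
            axis = axis / np.sqrt(np.einsum("ij,ij->i", axis, axis))[:, None]
            sign = next(
                st.var_sign for st in self.steps if st.var_index == v
            )
            rel = coords[:, aff] - coords[:, ic][:, None]
            Jv = J[:, :, :, v]
            Jv[:, aff] = _cross3(axis[:, None], rel) * (_D2R * sign)
        return J

    def _jacobian_fd(self, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
        base = np.atleast_3d(self.forward(x))
        if base.ndim == 2:
            base = base[None]
        S, N, _ = base.shape
        J = np.zeros((S, N, 3, self.n_var))
        for v in range(self.n_var):
            xp = x.copy()
            xp[:, v] += h
            cp = self.forward(xp)
            if cp.ndim == 2:
                cp = cp[None]
            J[:, :, :, v] = (cp - base) / h
        return J

    def check_geometry(self, coords: np.ndarray, tol: float = 1e-9) -> bool:
        """Verify bond lengths/angles of every step against the chain spec."""
        from .geometry import angle as _angle

        for i, st in enumerate(self.steps):
            d = coords[self.n_fixed + i]
            c = coords[st.frame[2]]
            b = coords[st.frame[1]]
            if abs(np.linalg.norm(d - c) - st.length) > tol:
                return False
            if abs(_angle(b, c, d) - st.angle) > max(tol * 180 / np.pi, 1e-7):
                return False
        return True


def _cross3(u, v):
    """Cross product for (..., 3) arrays without np.cross overhead."""
    out = np.empty(np.broadcast(u, v).shape)
    out[..., 0] = u[..., 1] * v[..., 2] - u[..., 2] * v[..., 1]
    out[..., 1] = u[..., 2] * v[..., 0] - u[..., 0] * v[..., 2]
    out[..., 2] = u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]
    return out


def _nerf_batch(a, b, c, length, angle_deg, torsion_deg):
    """Vectorized NeRF placement for (S,3) frames."""
    bc = c - b
    bc = bc / np.sqrt(np.einsum("ij,ij->i", bc, bc))[:, None]
    ab = b - a
    n = _cross3(ab, bc)
    n = n / np.sqrt(np.einsum("ij,ij->i", n, n))[:, None]
    m = _cross3(n, bc)
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    st = length * np.sin(theta)
    w_bc = -length * np.cos(theta)
    w_m = (st * np.cos(phi))[:, None]
    w_n = (st * np.sin(phi))[:, None]
    return c + bc * w_bc + m * w_m + n * w_n
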