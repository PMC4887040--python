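"""Loop-closure solvers: damped Gauss-Newton (quasi-Newton) and extended CCD.

Closure seeks torsion values for which the computed terminal backbone triple
(N, CA, C) of a kinematic loop coincides with its end anchor.  Acceptance
requires the terminal CA within the closure tolerance and the flanking N and
C atoms within twice the tolerance (otherwise the backbone frame, not just
the CA position, would be wrong).

The primary solver minimizes the squared terminal deviation over all free and
bounded torsions simultaneously using damped Gauss-Newton steps (a
quasi-Newton approximation of the Hessian by J^T J) with analytic torsion
gradients and projection onto torsion bounds; it is batched over multistart
seeds.  The extended-CCD baseline updates one torsion at a time by the
classic closed-form rotation that maximizes target alignment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .kinematics import wrap
from .loops import KinematicLoop

__all__ = [
    "ClosedLoop",
    "close_loop",
    "close_loop_multistart",
    "ccd_close_loop",
    "sample_initial_loops",
    "max_loop_length",
    "DEFAULT_CLOSURE_TOL",
]

DEFAULT_CLOSURE_TOL = 0.1  # Angstrom, terminal CA
_TARGET_WEIGHTS = np.array([0.7, 1.0, 0.7])  # N, CA, C


@dataclass
class ClosedLoop:
    torsions: np.ndarray
    closure_deviation: float  # terminal CA to target CA (A)
    orientation_deviation: float  # max of terminal N/C deviations (A)
    coords: np.ndarray  # all atoms of the chain, (F+P, 3)
    converged: bool

    def group_coords(self, loop: KinematicLoop) -> dict[str, dict[str, np.ndarray]]:
        """Placed coordinates keyed by group (role id / 'TS') and atom name."""
        out: dict[str, dict[str, np.ndarray]] = {}
        chain = loop.chain
        for group, idxs in chain.groups.items():
            out[group] = {
                chain.atom_names[i - chain.n_fixed].split(".", 1)[1]: self.coords[i]
                for i in idxs
            }
        return out


def _deviations(loop: KinematicLoop, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(dev_ca, dev_flank_max) for batched coords (S, N, 3)."""
    tg = loop.target_coords
    idx = loop.target_indices
    d = np.linalg.norm(coords[:, idx] - tg[None], axis=-1)  # (S, 3) order N, CA, C
    return d[:, 1], np.maximum(d[:, 0], d[:, 2])


def _accepted(loop, coords, tolerance):
    dev_ca, dev_fl = _deviations(loop, coords)
    return (dev_ca <= tolerance) & (dev_fl <= 2.0 * tolerance), dev_ca, dev_fl


def close_loop_batch(
    loop: KinematicLoop,
    X0: np.ndarray,
    tolerance: float = DEFAULT_CLOSURE_TOL,
    max_iter: int = 60,
    target_override: Optional[tuple[list[int], np.ndarray, np.ndarray]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Damped Gauss-Newton closure for a batch of torsion starts.

    Returns (X, converged) where X is the final torsion matrix.  With
    ``target_override=(indices, coords, weights)`` the solver minimizes the
    deviation of arbitrary chain atoms instead (used for max-reach runs; no
    convergence flag is meaningful there and all-False is returned).
    """
    chain = loop.chain
    X = np.atleast_2d(np.array(X0, dtype=float))
    S, V = X.shape
    lo, hi = chain.bounds()
    X = np.clip(X, lo, hi)
    if target_override is None:
        t_idx, t_coords, t_w = loop.target_indices, loop.target_coords, _TARGET_WEIGHTS
    else:
        t_idx, t_coords, t_w = target_override
        t_w = np.asarray(t_w, float)
    sw = np.repeat(np.sqrt(t_w), 3)

    def residuals(coords):
        return ((coords[:, t_idx] - t_coords[None]).reshape(S, -1)) * sw[None]

    lam = np.full(S, 1e-3)
    active = np.ones(S, dtype=bool)
    coords = chain.forward(X)
    R = residuals(coords)
    f = np.sum(R * R, axis=1)
    converged = np.zeros(S, dtype=bool)
    if target_override is None:
        ok, _, _ = _accepted(loop, coords, tolerance)
        converged |= ok
        active &= ~converged
    eye = np.eye(V)
    for _ in range(max_iter):
        if not active.any():
            break
        ia = np.where(active)[0]
        Jc = chain.jacobian(X[ia], coords[ia])  # (s, N, 3, V)
        J = (Jc[:, t_idx].reshape(len(ia), -1, V)) * sw[None, :, None]
        JtJ = np.einsum("sij,sik->sjk", J, J)
        JtR = np.einsum("sij,si->sj", J, R[ia])
        gnorm = np.linalg.norm(JtR, axis=1)
        accepted_any = np.zeros(len(ia), dtype=bool)
        for _retry in range(6):
            todo = ~accepted_any
            if not todo.any():
                break
            idx = ia[todo]
            A = JtJ[todo] + lam[idx][:, None, None] * eye[None]
            try:
                delta = -np.linalg.solve(A, JtR[todo][:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                delta = -np.linalg.solve(
                    A + 1e-6 * eye[None], JtR[todo][:, :, None]
                )[:, :, 0]
            Xt = np.clip(X[idx] + delta, lo, hi)
            ct = chain.forward(Xt)
            Rt = ((ct[:, t_idx] - t_coords[None]).reshape(len(idx), -1)) * sw[None]
            ft = np.sum(Rt * Rt, axis=1)
            better = ft < f[idx]
            bidx = idx[better]
            X[bidx] = Xt[better]
            coords[bidx] = ct[better]
            R[bidx] = Rt[better]
            f[bidx] = ft[better]
            lam[bidx] = np.maximum(lam[bidx] * 0.4, 1e-8)
            lam[idx[~better]] *= 5.0
            accepted_any[todo] = better
        # starts whose step failed 6 times in a row with tiny gradient stall out
        stalled = (~accepted_any) & ((lam[ia] > 1e7) | (gnorm < 1e-12))
        if target_override is None:
            ok, _, _ = _accepted(loop, coords, tolerance)
            newly = ok & active
            converged |= newly
            active &= ~newly
        active[ia[stalled]] = False
    return X, converged


def _to_closed(loop: KinematicLoop, x: np.ndarray, tolerance: float) -> ClosedLoop:
    coords = loop.chain.forward(x)
    dev_ca, dev_fl = _deviations(loop, coords[None])
    ok = bool(dev_ca[0] <= tolerance and dev_fl[0] <= 2 * tolerance)
    # wrap free torsions for reporting; bounded ones stay in their (possibly
    # beyond +/-180) interval around the constraint optimum
    x_out = x.copy()
    free = [i for i, v in enumerate(loop.chain.variables) if not v.bounded]
    x_out[free] = wrap(x_out[free])
    return ClosedLoop(
        torsions=x_out,
        closure_deviation=float(dev_ca[0]),
        orientation_deviation=float(dev_fl[0]),
        coords=coords,
        converged=ok,
    )


def close_loop(
    loop: KinematicLoop,
    initial_torsions,
    tolerance: float = DEFAULT_CLOSURE_TOL,
    max_iter: int = 60,
) -> Optional[ClosedLoop]:
    """Close a loop from one start; returns None if not converged."""
    X, conv = close_loop_batch(loop, np.atleast_2d(initial_torsions), tolerance, max_iter)
    closed = _to_closed(loop, X[0], tolerance)
    return closed if conv[0] and closed.converged else None


def close_loop_multistart(
    loop: KinematicLoop,
    starts: np.ndarray,
    tolerance: float = DEFAULT_CLOSURE_TOL,
    max_iter: int = 60,
) -> list[ClosedLoop]:
    """Close from every start; returns the converged solutions in start order."""
    if len(starts) == 0:
        return []
    X, conv = close_loop_batch(loop, starts, tolerance, max_iter)
    out = []
    for i in np.where(conv)[0]:
        closed = _to_closed(loop, X[i], tolerance)
        if closed.converged:
            out.append(closed)
    return out


def ccd_close_loop(
    loop: KinematicLoop,
    initial_torsions,
    tolerance: float = DEFAULT_CLOSURE_TOL,
    max_cycles: int = 120,
) -> Optional[ClosedLoop]:
    """Extended cyclic-coordinate-descent closure (one torsion at a time).

    Each update rotates all downstream atoms about one torsion axis by the
    closed-form angle that best aligns the three terminal backbone atoms with
    the anchor; bounded torsions are clamped to their ranges.
    """
    chain = loop.chain
    x = np.array(initial_torsions, dtype=float)
    lo, hi = chain.bounds()
    x = np.clip(x, lo, hi)
    t_idx = np.array(loop.target_indices)
    t_coords = loop.target_coords
    w = _TARGET_WEIGHTS
    for _cycle in range(max_cycles):
        coords = chain.forward(x)
        ok, _, _ = _accepted(loop, coords[None], tolerance)
        if ok[0]:
            return _to_closed(loop, x, tolerance)
        moved = False
        for v in range(chain.n_var):
            aff = chain._var_affected[v]
            hit = [k for k, t in enumerate(t_idx) if t in aff]
            if not hit:
                continue
            ib, ic = chain._var_axis[v]
            coords = chain.forward(x)
            u = coords[ic] - coords[ib]
            nu = np.linalg.norm(u)
            if nu < 1e-9:
                continue
            u /= nu
            a = b = 0.0
            for k in hit:
                p = coords[t_idx[k]] - coords[ic]
                q = t_coords[k] - coords[ic]
                p_par = np.dot(p, u) * u
                s = p - p_par
                a += w[k] * np.dot(s, q)
                b += w[k] * np.dot(np.cross(u, s), q)
            if abs(a) < 1e-15 and abs(b) < 1e-15:
                continue
            phi = np.degrees(np.arctan2(b, a))
            sign = next(st.var_sign for st in chain.steps if st.var_index == v)
            newv = float(np.clip(x[v] + sign * phi, lo[v], hi[v]))
            if abs(newv - x[v]) > 1e-12:
                x[v] = newv
                moved = True
        if not moved:
            break
    closed = _to_closed(loop, x, tolerance)
    return closed if closed.converged else None


def sample_initial_loops(
    loop: KinematicLoop,
    grid_step: float = 120.0,
    max_samples: int = 128,
    seed: int = 0,
) -> np.ndarray:
    """Deterministic multistart torsion vectors.

    Free torsions enumerate a grid (``grid_step`` for sp3-like, 180 deg for
    sp2-like); bounded torsions are seeded at their optimum.  If the grid
    exceeds ``max_samples``, a reproducible uniform subsample is drawn.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    grids = [v.grid(step_sp3=grid_step) for v in loop.chain.variables]
    sizes = np.array([len(g) for g in grids], dtype=np.int64)
    total = int(np.prod(sizes)) if len(sizes) else 1
    if total <= max_samples:
        combos = np.array(list(itertools.product(*grids)))
        return combos.reshape(total, loop.chain.n_var)
    rng = np.random.default_rng(seed)
    pick = np.sort(rng.choice(total, size=max_samples, replace=False))
    out = np.empty((max_samples, loop.chain.n_var))
    for j, flat in enumerate(pick):
        rem = int(flat)
        for v in range(len(grids) - 1, -1, -1):
            rem, k = divmod(rem, sizes[v])
            out[j, v] = grids[v][k]
    return out


def max_loop_length(
    loop: KinematicLoop,
    seed: int = 0,
    n_starts: int = 24,
    n_random: int = 512,
    max_iter: int = 80,
    safety: float = 2e-3,
) -> float:
    """Theoretical maximum reach of a loop (start CA to computed terminal CA).

    Implements the dummy-target construction: a phantom CA is placed 1,000 A
    from the starting CA along the start-to-anchor direction and the closure
    optimizer is run against it from a multistart (grid starts plus the most
    extended random conformations); the largest achieved start-to-terminal
    distance, inflated by a small relative ``safety`` factor to cover
    optimizer slack, is the bound.
    """
    chain = loop.chain
    start = loop.start_ca_coord
    d = loop.target_coords[1] - start
    nd = np.linalg.norm(d)
    u = d / nd if nd > 1e-9 else np.array([1.0, 0.0, 0.0])
    dummy = start + 1000.0 * u

    grid_starts = sample_initial_loops(loop, max_samples=n_starts, seed=seed)
    rng = np.random.default_rng(seed + 1)
    lo, hi = chain.bounds()
    lo_s = np.where(np.isfinite(lo), lo, -180.0)
    hi_s = np.where(np.isfinite(hi), hi, 180.0)
    randoms = rng.uniform(lo_s, hi_s, size=(n_random, chain.n_var))
    tidx = loop.terminal_ca_index

    def reach_of(X):
        coords = chain.forward(X)
        if coords.ndim == 2:
            coords = coords[None]
        return np.linalg.norm(coords[:, tidx] - start, axis=-1)

    r_rand = reach_of(randoms)
    top = randoms[np.argsort(r_rand)[-8:]]
    starts = np.vstack([grid_starts, top])
    best = float(np.max(r_rand))
    X, _ = close_loop_batch(
        loop, starts, tolerance=0.0, max_iter=max_iter,
        target_override=([tidx], dummy[None], np.array([1.0])),
    )
    r_opt = reach_of(X)
    best = max(best, float(np.max(r_opt)))
    # cyclic 1-D polish of the most extended candidates: the constrained
    # maximum often sits on a torsion bound where Gauss-Newton steps stall
    for k in np.argsort(r_opt)[-3:]:
        x = X[k].copy()
        for _sweep in range(3):
            for v in range(chain.n_var):
                grid = np.linspace(lo_s[v], hi_s[v], 49)
                cand = np.repeat(x[None], len(grid), axis=0)
                cand[:, v] = grid
                rr = reach_of(cand)
                x[v] = grid[int(np.argmax(rr))]
        best = max(best, float(reach_of(x[None])[0]))
    return best * (1.0 + safety)
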