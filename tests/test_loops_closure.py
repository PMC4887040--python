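import numpy as np
import pytest

from enzymatch.closure import (
    ccd_close_loop,
    close_loop,
    close_loop_multistart,
    max_loop_length,
    sample_initial_loops,
)
from enzymatch.loops import build_loops, build_main_loop, main_loop_roles
from enzymatch.motif import CatalyticMotif, GeometricConstraint


def _planted_main_loop(fx):
    r1, r2 = main_loop_roles(fx.motif)
    s1 = fx.scaffold.get(fx.truth.assignment[r1])
    s2 = fx.scaffold.get(fx.truth.assignment[r2])
    return build_main_loop(fx.motif, fx.scaffold, r1, s1, r2, s2), r1, r2


def test_build_loops_structure(planted):
    """One main loop through two side-chain roles + one side loop per
    remaining role."""
    main, sides = build_loops(planted.motif, planted.truth.assignment, planted.scaffold)
    assert main.kind == "main"
    assert main.includes_ts
    assert len(sides) == len(planted.motif.residues) - 2
    # free torsions: role-1 chi-like + role-2 reversed chi torsions; every
    # constraint dihedral with finite tolerance is bounded at its optimum
    for i in main.bounded_torsions:
        v = main.chain.variables[i]
        assert v.lower is not None and v.lower <= v.seed <= v.upper
    assert len(main.free_torsions) == 4  # Ser chi1 + Ser-O torsion + His rev chi2/chi1


def test_backbone_role_cannot_anchor_main_loop(planted):
    motif = planted.motif
    sid = planted.truth.assignment["ALA4"]
    with pytest.raises(ValueError, match="backbone"):
        build_main_loop(
            motif, planted.scaffold, "ALA4", planted.scaffold.get(sid),
            "HIS2", planted.scaffold.get(planted.truth.assignment["HIS2"]),
        )


def test_assignment_must_be_injective(planted):
    assignment = dict(planted.truth.assignment)
    assignment["ASP3"] = assignment["SER1"]
    with pytest.raises(ValueError, match="distinct"):
        build_loops(planted.motif, assignment, planted.scaffold)


def test_closure_fixed_point(planted):
    """Starting from the planted (exactly closed) torsions, the solver
    converges immediately and does not move."""
    loop, r1, r2 = _planted_main_loop(planted)
    xstar = planted.truth.torsions[f"{r1}+{r2}"]
    closed = close_loop(loop, xstar)
    assert closed is not None
    assert closed.closure_deviation <= 1e-9
    assert closed.orientation_deviation <= 1e-9
    # the solver accepted the start without moving it
    from enzymatch.kinematics import wrap

    assert np.allclose(closed.torsions, wrap(xstar), atol=1e-9)


def test_closure_preserves_bond_geometry(planted):
    loop, r1, r2 = _planted_main_loop(planted)
    xstar = planted.truth.torsions[f"{r1}+{r2}"]
    rng = np.random.default_rng(11)
    lo, hi = loop.chain.bounds()
    x0 = np.clip(xstar + rng.uniform(-20, 20, loop.chain.n_var), lo, hi)
    closed = close_loop(loop, x0)
    assert closed is not None
    assert loop.chain.check_geometry(closed.coords, tol=1e-9)
    # bounded torsions stay in range
    assert np.all(closed.torsions >= lo - 1e-9) and np.all(closed.torsions <= hi + 1e-9)


def test_perturbation_recovery_and_ccd_comparison(planted):
    """Perturbed planted loops re-close to within tolerance; the quasi-Newton
    solver succeeds at least as often as extended CCD on paired trials."""
    loop, r1, r2 = _planted_main_loop(planted)
    xstar = planted.truth.torsions[f"{r1}+{r2}"]
    lo, hi = loop.chain.bounds()
    rng = np.random.default_rng(0)
    n_q = n_c = 0
    trials = 30
    for _ in range(trials):
        x0 = np.clip(xstar + rng.uniform(-20, 20, loop.chain.n_var), lo, hi)
        cq = close_loop(loop, x0, tolerance=0.1)
        cc = ccd_close_loop(loop, x0, tolerance=0.1)
        if cq is not None:
            assert cq.closure_deviation <= 0.1
            n_q += 1
        if cc is not None:
            assert cc.closure_deviation <= 0.1
            n_c += 1
    assert n_q >= int(0.9 * trials)
    assert n_q >= n_c


def test_sample_initial_loops_counts_and_determinism(planted):
    loop, _, _ = _planted_main_loop(planted)
    starts = sample_initial_loops(loop, grid_step=120.0, max_samples=1000, seed=0)
    # full grid: product of per-variable start counts
    expected = 1
    for v in loop.chain.variables:
        expected *= len(v.grid())
    assert starts.shape == (expected, loop.chain.n_var)
    assert np.array_equal(starts, sample_initial_loops(loop, 120.0, 1000, 0))
    # subsampling cap: reproducible, distinct rows
    capped = sample_initial_loops(loop, 120.0, max_samples=10, seed=5)
    assert capped.shape == (10, loop.chain.n_var)
    assert np.array_equal(capped, sample_initial_loops(loop, 120.0, 10, 5))
    assert len({tuple(r) for r in capped}) == 10
    with pytest.raises(ValueError):
        sample_initial_loops(loop, grid_step=0.0)


def test_three_sp3_torsions_give_27_starts(planted):
    """A loop with exactly three free sp3 torsions enumerates 3^3 starts."""
    main, sides = build_loops(planted.motif, planted.truth.assignment, planted.scaffold)
    asp = next(s for s in sides if s.role_id == "ASP3")
    partner = {"TS": planted.truth.ts_pose, **planted.truth.conformations}
    loop = asp.bind(partner["HIS2"], planted.scaffold.get(planted.truth.assignment["ASP3"]))
    free = [loop.chain.variables[i] for i in loop.free_torsions]
    sp3 = [v for v in free if v.grid_kind == "sp3"]
    if len(sp3) == len(free) == 3:
        starts = sample_initial_loops(loop, 120.0, 1000, 0)
        assert len(starts) == 27


def test_max_reach_monte_carlo_soundness(planted):
    loop, _, _ = _planted_main_loop(planted)
    bound = max_loop_length(loop, seed=0)
    lo, hi = loop.chain.bounds()
    lo = np.where(np.isfinite(lo), lo, -180.0)
    hi = np.where(np.isfinite(hi), hi, 180.0)
    X = np.random.default_rng(99).uniform(lo, hi, (1000, loop.chain.n_var))
    coords = loop.chain.forward(X)
    reach = np.linalg.norm(coords[:, loop.terminal_ca_index] - loop.start_ca_coord, axis=-1)
    assert float(reach.max()) <= bound


def test_widening_a_torsion_bound_never_decreases_reach(planted):
    """Freeing a bounded torsion can only extend the reachable envelope."""
    motif = planted.motif
    loosened = CatalyticMotif(
        motif.name + "_loose",
        motif.residues,
        motif.ts,
        [
            GeometricConstraint(c.kind, c.atom_refs, c.optimal, 180.0, c.periodic)
            if c.kind in ("dihedral", "improper_dihedral")
            else c
            for c in motif.constraints
        ],
    )
    r1, r2 = main_loop_roles(motif)
    s1 = planted.scaffold.get(planted.truth.assignment[r1])
    s2 = planted.scaffold.get(planted.truth.assignment[r2])
    tight = build_main_loop(motif, planted.scaffold, r1, s1, r2, s2)
    loose = build_main_loop(loosened, planted.scaffold, r1, s1, r2, s2)
    assert len(loose.free_torsions) >= len(tight.free_torsions)
    r_tight = max_loop_length(tight, seed=0)
    r_loose = max_loop_length(loose, seed=0)
    assert r_loose >= r_tight - 0.02  # small numerical slack


def test_main_loop_reversal_symmetry(planted):
    """Swapping the two main-loop roles yields a loop that closes onto the
    same planted geometry (solution sets map 1:1)."""
    motif = planted.motif
    r1, r2 = main_loop_roles(motif)
    s1 = planted.scaffold.get(planted.truth.assignment[r1])
    s2 = planted.scaffold.get(planted.truth.assignment[r2])
    fwd = build_main_loop(motif, planted.scaffold, r1, s1, r2, s2)
    rev = build_main_loop(motif, planted.scaffold, r2, s2, r1, s1)
    tol = 0.05

    def ts_poses(loop):
        starts = sample_initial_loops(loop, 120.0, 256, 0)
        out = []
        for c in close_loop_multistart(loop, starts, tolerance=tol):
            grp = c.group_coords(loop)
            out.append({n: grp["TS"][n] for n in grp["TS"]})
        return out

    fwd_poses = ts_poses(fwd)
    rev_poses = ts_poses(rev)
    assert fwd_poses and rev_poses
    truth = planted.truth.ts_pose

    def best_err(poses):
        return min(
            max(np.linalg.norm(p[n] - truth[n]) for n in truth) for p in poses
        )

    # both directions recover the planted TS pose
    assert best_err(fwd_poses) < 0.1
    assert best_err(rev_poses) < 0.1


def test_unreachable_anchors_never_close(planted):
    """Anchors separated beyond the maximum reach admit no closed loop."""
    from enzymatch.structure import ProteinStructure, Residue

    loop, r1, r2 = _planted_main_loop(planted)
    bound = max_loop_length(loop, seed=0)
    s1 = planted.scaffold.get(planted.truth.assignment[r1])
    far = Residue("Z", 1, "HIS")
    shift = np.array([bound + 8.0, 0.0, 0.0])
    s2 = planted.scaffold.get(planted.truth.assignment[r2])
    for n in ("N", "CA", "C"):
        far.set_atom(n, s2.coord(n) + shift)
    scaffold = ProteinStructure(residues=[s1, far])
    stretched = build_main_loop(planted.motif, scaffold, r1, s1, r2, far)
    starts = sample_initial_loops(stretched, 120.0, 128, 0)
    assert close_loop_multistart(stretched, starts, tolerance=0.1) == []
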