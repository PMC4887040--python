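import numpy as np
import pytest

from enzymatch.closure import max_loop_length, sample_initial_loops, close_loop_multistart
from enzymatch.loops import build_loops, build_main_loop, main_loop_roles
from enzymatch.pruning import (
    PruningParams,
    RepulsionModel,
    dedup_loops,
    prune_by_reach,
    prune_by_repulsion,
    repulsion_energy,
)


def test_reach_pruning_trivial_cases(planted):
    main, _ = build_loops(planted.motif, planted.truth.assignment, planted.scaffold)
    reach = max_loop_length(main, seed=0)
    params = PruningParams()
    # sites far beyond any possible reach -> prune
    assert not prune_by_reach(
        [np.zeros(3), np.array([reach + 30.0, 0, 0])], main, params, reach=reach
    )
    # planted site pair -> keep (reach covers the actual distance)
    r1, r2 = main_loop_roles(planted.motif)
    ca1 = planted.scaffold.get(planted.truth.assignment[r1]).coord("CA")
    ca2 = planted.scaffold.get(planted.truth.assignment[r2]).coord("CA")
    assert prune_by_reach([ca1, ca2], main, params, reach=reach)


def test_reach_pruning_is_conservative(planted):
    """A reach-pruned site pair admits no closed constraint-satisfying loop
    under exhaustive multistart (pruning-i soundness oracle)."""
    from enzymatch.structure import ProteinStructure, Residue

    r1, r2 = main_loop_roles(planted.motif)
    s1 = planted.scaffold.get(planted.truth.assignment[r1])
    s2 = planted.scaffold.get(planted.truth.assignment[r2])
    main = build_main_loop(planted.motif, planted.scaffold, r1, s1, r2, s2)
    reach = max_loop_length(main, seed=0)
    for extra in (1.0, 4.0):
        far = Residue("Z", 1, s2.name)
        direction = s2.coord("CA") - s1.coord("CA")
        direction = direction / np.linalg.norm(direction)
        target_ca = s1.coord("CA") + direction * (reach + PruningParams().reach_margin + extra)
        shift = target_ca - s2.coord("CA")
        for n in ("N", "CA", "C"):
            far.set_atom(n, s2.coord(n) + shift)
        assert not prune_by_reach([s1.coord("CA"), far.coord("CA")],
                                  main, PruningParams(), reach=reach)
        scaffold = ProteinStructure(residues=[s1, far])
        loop = build_main_loop(planted.motif, scaffold, r1, s1, r2, far)
        starts = sample_initial_loops(loop, grid_step=60.0, max_samples=600, seed=0)
        assert close_loop_multistart(loop, starts, tolerance=0.1) == []


def test_dedup_identical_and_distant(planted):
    main, _ = build_loops(planted.motif, planted.truth.assignment, planted.scaffold)
    starts = sample_initial_loops(main, 120.0, 128, 0)
    closed = close_loop_multistart(main, starts, tolerance=0.1)
    assert len(closed) >= 2
    # two identical loops collapse to one
    assert len(dedup_loops([closed[0], closed[0]], threshold=0.5)) == 1
    kept = dedup_loops(closed, threshold=0.5)

    def rmsd(a, b):
        return float(np.sqrt(np.mean(np.sum((a.coords - b.coords) ** 2, axis=1))))

    # oracle recheck: every kept pair is separated, every discarded loop has a
    # kept neighbour within the threshold
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            assert rmsd(kept[i], kept[j]) > 0.5
    kept_ids = {id(k) for k in kept}
    for c in closed:
        if id(c) not in kept_ids:
            assert any(rmsd(c, k) <= 0.5 for k in kept)
    # loops at pairwise RMSD > threshold are all kept
    assert len(dedup_loops(kept, threshold=0.5)) == len(kept)


def test_dedup_matches_independent_greedy_oracle(planted, rng):
    main, _ = build_loops(planted.motif, planted.truth.assignment, planted.scaffold)
    starts = sample_initial_loops(main, 120.0, 128, 0)
    closed = close_loop_multistart(main, starts, tolerance=0.1)
    order = rng.permutation(len(closed))
    loops = [closed[i] for i in order]
    kept = dedup_loops(loops, threshold=0.8)
    # independent greedy recomputation
    expected = []
    for c in loops:
        if all(
            np.sqrt(np.mean(np.sum((c.coords - k.coords) ** 2, axis=1))) > 0.8
            for k in expected
        ):
            expected.append(c)
    assert [id(k) for k in kept] == [id(e) for e in expected]


def test_repulsion_closed_form():
    model = RepulsionModel(k=10.0, c=0.85)
    a = [(np.zeros(3), 1.9)]
    # separated by 10 A -> zero
    assert repulsion_energy(a, [(np.array([10.0, 0, 0]), 1.9)], model) == 0.0
    # fully overlapping pair -> exactly k
    assert repulsion_energy(a, [(np.zeros(3), 1.9)], model) == pytest.approx(10.0)
    # halfway to onset -> k/2
    onset = 0.85 * 3.8
    assert repulsion_energy(
        a, [(np.array([onset / 2, 0, 0]), 1.9)], model
    ) == pytest.approx(5.0)


def test_repulsion_monotone_under_separation():
    """Once the two sets are disjoint along the separation axis, every pair
    distance grows with the shift, so the repulsion cannot increase."""
    local = np.random.default_rng(42)
    model = RepulsionModel()
    A = [(p, 1.8) for p in local.uniform(-1, 1, size=(6, 3))]
    base = [(p + np.array([2.5, 0.0, 0.0]), 1.7) for p in local.uniform(-1, 1, size=(5, 3))]
    prev = np.inf
    for d in np.linspace(0.0, 8.0, 30):
        B = [(p + np.array([d, 0.0, 0.0]), r) for p, r in base]
        e = repulsion_energy(A, B, model)
        assert e >= 0.0
        assert e <= prev + 1e-9
        prev = e
    assert repulsion_energy(A, [(p + np.array([20.0, 0, 0]), r) for p, r in base], model) == 0.0


def test_repulsion_requires_radius():
    class NoRadius:
        coords = np.zeros(3)
        vdw_radius = None
        name = "X"

    with pytest.raises(ValueError, match="radius"):
        repulsion_energy([NoRadius()], [(np.zeros(3), 1.0)])


@pytest.mark.parametrize(
    "stage,energy,keep",
    [
        ("main_loop", 149.0, True),
        ("main_loop", 151.0, False),
        ("side_loop", 29.0, True),
        ("side_loop", 31.0, False),
        ("match_vs_template", 199.0, True),
        ("match_vs_template", 201.0, False),
        ("match_vs_backbone", 49.0, True),
        ("match_vs_backbone", 51.0, False),
        ("main_loop", 0.0, True),
    ],
)
def test_repulsion_thresholds(stage, energy, keep):
    assert prune_by_repulsion(stage, energy, PruningParams()) is keep


def test_unknown_stage_rejected():
    with pytest.raises(ValueError):
        prune_by_repulsion("nonsense", 0.0, PruningParams())


def test_planted_truth_passes_all_pruning_stages(matched_pool):
    """Calibration requirement: no planted ground-truth match is eliminated
    by any pruning stage at default thresholds."""
    params = PruningParams()
    for fx, matches in matched_pool:
        truth_matches = [m for m in matches if m.site_assignment == fx.truth.assignment]
        assert truth_matches, f"planted match pruned in fixture seed {fx.seed}"
        m = truth_matches[0]
        assert m.repulsion["main_loop"] <= params.main_loop_backbone_max
        for key, val in m.repulsion.items():
            if key.startswith("side:"):
                assert val <= params.side_loop_backbone_max
        assert m.repulsion["match_vs_template"] <= params.match_template_max
        assert m.repulsion["match_vs_backbone"] <= params.match_backbone_max
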