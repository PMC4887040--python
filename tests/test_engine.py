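import numpy as np
import pytest

from enzymatch.engine import (
    Match,
    MatchConfig,
    enumerate_assignments,
    match_scaffold,
    rank_matches,
    ts_rmsd_vs_reference,
)
from enzymatch.motif import CatalyticMotif, GeometricConstraint


def test_enumerate_assignments_counts(planted):
    """3 roles on 5 usable sites without pruning -> 5*4*3 injective maps."""
    minimal = planted.motif.minimal_view()
    sites = [r for r in planted.scaffold.residues if not r.is_proline][:5]
    maps = list(enumerate_assignments(minimal, sites))
    assert len(maps) == 60
    assert all(len(set(m.values())) == 3 for m in maps)
    # deterministic order
    maps2 = list(enumerate_assignments(minimal, sites))
    assert maps == maps2


def test_enumerate_assignments_respects_pruned_pairs(planted):
    minimal = planted.motif.minimal_view()
    sites = [r for r in planted.scaffold.residues if not r.is_proline][:5]
    pruned = {(sites[0].res_id, sites[1].res_id)}
    maps = list(enumerate_assignments(minimal, sites, pruned_pairs=pruned))
    # brute-force filtered count
    expected = [
        m for m in enumerate_assignments(minimal, sites)
        if not (m["SER1"] == sites[0].res_id and m["HIS2"] == sites[1].res_id)
    ]
    assert maps == expected
    assert len(maps) == 60 - 3  # 3 remaining choices for ASP3


def test_enumerate_assignments_pigeonhole(planted):
    minimal = planted.motif.minimal_view()
    sites = [r for r in planted.scaffold.residues if not r.is_proline][:2]
    assert list(enumerate_assignments(minimal, sites)) == []


def _fake_match(rms, rep, labels):
    from enzymatch.motif import ConstraintReport

    return Match(
        scaffold_id="x",
        site_assignment={"R1": ("A", labels, "")},
        ts_pose={"C1": np.zeros(3)},
        residue_conformations={},
        constraint_report=ConstraintReport([], True, rms),
        repulsion={"match_vs_backbone": rep},
    )


def test_rank_matches_order_and_determinism(rng):
    ms = [_fake_match(rms, rep, i) for i, (rms, rep) in
          enumerate([(0.5, 10.0), (0.0, 0.0), (0.1, 300.0), (0.1, 5.0)])]
    ranked = rank_matches(list(ms))
    # zero-deviation zero-repulsion match ranks first
    assert ranked[0].constraint_report.rms_deviation == 0.0
    # brute-force sort oracle
    expected = sorted(
        ms, key=lambda m: (m.constraint_report.rms_deviation + m.repulsion_total / 100,
                           m.repulsion_total,
                           tuple(sorted(m.site_assignment.items())))
    )
    assert [id(m) for m in ranked] == [id(m) for m in expected]
    # permuting input order does not change the output
    perm = [ms[i] for i in rng.permutation(len(ms))]
    assert [id(m) for m in rank_matches(perm)] == [id(m) for m in ranked]
    # idempotent
    assert [id(m) for m in rank_matches(ranked)] == [id(m) for m in ranked]


def test_ts_rmsd_translation_and_oracle(matched_pool, rng):
    fx, matches = matched_pool[0]
    m = matches[0]
    assert ts_rmsd_vs_reference(m, fx.truth.ts_pose) < 1e-6
    shifted = {k: v + np.array([1.0, 0.0, 0.0]) for k, v in fx.truth.ts_pose.items()}
    assert ts_rmsd_vs_reference(m, shifted) == pytest.approx(1.0, abs=1e-9)
    # random perturbation equals the brute-force RMSD formula
    noise = {k: v + rng.normal(0, 0.3, 3) for k, v in fx.truth.ts_pose.items()}
    names = sorted(n for n in m.ts_pose if not n.startswith("H"))
    brute = np.sqrt(np.mean([np.sum((m.ts_pose[n] - noise[n]) ** 2) for n in names]))
    assert ts_rmsd_vs_reference(m, noise) == pytest.approx(brute, abs=1e-12)
    with pytest.raises(KeyError):
        ts_rmsd_vs_reference(m, {"C1": np.zeros(3)})


def test_planted_recovery_rank1(matched_pool):
    """The planted assignment is found, ranked first, with a sub-0.5-A no-fit
    TS RMSD (the desk-scale recapitulation analogue)."""
    for fx, matches in matched_pool:
        assert matches, f"no matches for fixture {fx.seed}"
        top = matches[0]
        assert top.site_assignment == fx.truth.assignment
        assert ts_rmsd_vs_reference(top, fx.truth.ts_pose) < 0.5
        # every emitted match satisfies all constraints and all thresholds
        for m in matches:
            assert m.constraint_report.all_satisfied
            assert len(set(m.site_assignment.values())) == len(m.site_assignment)


def test_match_determinism(planted):
    cfg = MatchConfig(seed=0)
    m1 = match_scaffold(planted.scaffold, planted.motif, cfg,
                        reference_residues=planted.catalytic_site_ids)
    m2 = match_scaffold(planted.scaffold, planted.motif, cfg,
                        reference_residues=planted.catalytic_site_ids)
    assert len(m1) == len(m2)
    for a, b in zip(m1, m2):
        assert a.site_assignment == b.site_assignment
        assert a.rank_score == b.rank_score
        for n in a.ts_pose:
            assert np.array_equal(a.ts_pose[n], b.ts_pose[n])


def test_shifted_motif_yields_no_matches(planted):
    """Negative control: shifting every constraint optimum by five tolerances
    leaves nothing to match."""
    shifted = CatalyticMotif(
        planted.motif.name + "_shifted",
        planted.motif.residues,
        planted.motif.ts,
        [
            GeometricConstraint(c.kind, c.atom_refs, c.optimal + 5 * c.tolerance,
                                c.tolerance, c.periodic)
            for c in planted.motif.constraints
        ],
    )
    out = match_scaffold(planted.scaffold, shifted, MatchConfig(seed=0),
                         reference_residues=planted.catalytic_site_ids)
    assert out == []


def test_complex_model_matches_are_a_subset(planted):
    """The complex model's extra constraints can only remove matches relative
    to the minimal (catalytic-residues-only) model."""
    cfg = MatchConfig(seed=0)
    complex_matches = match_scaffold(planted.scaffold, planted.motif, cfg,
                                     reference_residues=planted.catalytic_site_ids)
    minimal_matches = match_scaffold(planted.scaffold, planted.motif.minimal_view(), cfg,
                                     reference_residues=planted.catalytic_site_ids)
    assert len(complex_matches) <= len(minimal_matches)
    # catalytic sub-assignment of every complex match appears among minimal ones
    minimal_assignments = {
        tuple(sorted(m.site_assignment.items())) for m in minimal_matches
    }
    for m in complex_matches:
        sub = tuple(sorted(
            (k, v) for k, v in m.site_assignment.items() if k in ("SER1", "HIS2", "ASP3")
        ))
        assert sub in minimal_assignments
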