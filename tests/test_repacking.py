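import itertools

import numpy as np
import pytest

from enzymatch.energy import AtomRecord, annotate_records, interaction_energy
from enzymatch.repacking import (
    EnergyTable,
    Rotamer,
    SiteRotamers,
    binding_energy,
    build_energy_tables,
    dee_reduce,
    default_rotamer_library,
    detect_hydrogen_bonds,
    expand_hydroxyl_rotamers,
    hbond_recovery,
    load_rotamer_library,
    residue_records,
    solve_gmec,
    ts_records,
)
from enzymatch.structure import design_sites
from enzymatch.templates import N_CHI


# ---------------------------------------------------------------------------
# rotamer library


def test_default_library_counts_match_chi_definitions():
    lib = default_rotamer_library()
    for aa, rots in lib.rotamers.items():
        for r in rots:
            assert len(r.chis) == N_CHI[aa]
    assert lib.n_rotamers() > 50


def test_hydroxyl_expansion_counts():
    lib = default_rotamer_library()
    n_ser = len(lib.for_aa("SER"))
    n_leu = len(lib.for_aa("LEU"))
    for step in (120.0, 60.0):
        ex = expand_hydroxyl_rotamers(lib, step)
        assert len(ex.for_aa("SER")) == n_ser * int(360 / step)
        assert len(ex.for_aa("LEU")) == n_leu  # non-hydroxyl residues untouched
    with pytest.raises(ValueError):
        expand_hydroxyl_rotamers(lib, 100.0)  # does not divide 360


def test_hydroxyl_expansion_preserves_heavy_atoms(planted):
    from enzymatch.repacking import place_rotamer

    lib = expand_hydroxyl_rotamers(default_rotamer_library(), 120.0)
    ser_site = next(r for r in planted.scaffold.residues if r.name == "SER")
    variants = [r for r in lib.for_aa("SER") if r.chis == (-60.0,)]
    assert len(variants) == 3
    placed = [place_rotamer(ser_site, v) for v in variants]
    heavy = [
        {n: c for n, c in p.items() if not n.startswith("H")} for p in placed
    ]
    for other in heavy[1:]:
        for n, c in heavy[0].items():
            assert np.allclose(c, other[n], atol=1e-12)
    # hydroxyl hydrogens differ
    hg = [p["HG1"] for p in placed]
    assert np.linalg.norm(hg[0] - hg[1]) > 0.3


def test_load_rejects_wrong_chi_count():
    with pytest.raises(ValueError):
        load_rotamer_library("SER -60 120\n")


# ---------------------------------------------------------------------------
# DEE + GMEC


def _random_table(rng, n_sites=4, n_rot=6):
    sites = [
        SiteRotamers((chr(65), i, ""), f"A{i}", "XXX",
                     [Rotamer((float(k),)) for k in range(n_rot)], [])
        for i in range(n_sites)
    ]
    singleton = [rng.normal(scale=3.0, size=n_rot) for _ in range(n_sites)]
    pairwise = {
        (i, j): rng.normal(scale=1.5, size=(n_rot, n_rot))
        for i in range(n_sites)
        for j in range(i + 1, n_sites)
    }
    return EnergyTable(sites, singleton, pairwise)


def _exhaustive_gmec(table):
    sizes = [len(s.rotamers) for s in table.sites]
    best, best_e = None, np.inf
    for combo in itertools.product(*(range(n) for n in sizes)):
        e = table.assignment_energy(combo)
        if e < best_e:
            best, best_e = combo, e
    return list(best), best_e


@pytest.mark.parametrize("seed", range(5))
def test_dee_preserves_gmec_random_instances(seed):
    """DEE + exact solve equals exhaustive enumeration (the module's core
    oracle), on batches of random 4-site x 6-rotamer instances."""
    rng = np.random.default_rng(seed)
    for _ in range(20):
        table = _random_table(rng)
        ref_assign, ref_e = _exhaustive_gmec(table)
        reduced = dee_reduce(table)
        assert reduced.n_combinations() <= table.n_combinations()
        assign, e = solve_gmec(reduced)
        assert e == pytest.approx(ref_e, abs=1e-9)
        # map reduced indices back to chi tags to compare assignments
        chosen = [reduced.sites[i].rotamers[r].chis for i, r in enumerate(assign)]
        expected = [table.sites[i].rotamers[r].chis for i, r in enumerate(ref_assign)]
        assert chosen == expected


def test_dee_eliminates_uniformly_dominated_rotamer(rng):
    table = _random_table(rng, n_sites=3, n_rot=4)
    # make rotamer 0 at site 0 strictly dominated by rotamer 1 everywhere
    table.singleton[0][0] = table.singleton[0][1] + 5.0
    for (i, j), m in table.pairwise.items():
        if i == 0:
            m[0, :] = m[1, :] + 1.0
    reduced = dee_reduce(table)
    assert (0.0,) not in [r.chis for r in reduced.sites[0].rotamers]


def test_single_rotamer_sites_unchanged(rng):
    table = _random_table(rng, n_sites=3, n_rot=1)
    reduced = dee_reduce(table)
    assert reduced.n_combinations() == 1
    assign, e = solve_gmec(reduced)
    assert assign == [0, 0, 0]


def test_single_site_gmec_is_argmin(rng):
    table = _random_table(rng, n_sites=1, n_rot=6)
    table.pairwise.clear()
    assign, e = solve_gmec(table)
    assert assign[0] == int(np.argmin(table.singleton[0]))


def test_gmec_gauge_invariance(rng):
    table = _random_table(rng)
    a0, e0 = solve_gmec(dee_reduce(table))
    chosen0 = [table.sites[i].rotamers[r].chis for i, r in
               enumerate(_exhaustive_gmec(table)[0])]
    table.singleton[2] = table.singleton[2] + 7.5
    a1, e1 = solve_gmec(dee_reduce(table))
    assert e1 == pytest.approx(e0 + 7.5, abs=1e-9)


def test_milp_agrees_with_exhaustive(rng):
    from enzymatch.repacking import _solve_milp

    table = _random_table(rng, n_sites=4, n_rot=5)
    ref_assign, ref_e = _exhaustive_gmec(table)
    assign, e = _solve_milp(table)
    assert e == pytest.approx(ref_e, abs=1e-6)


# ---------------------------------------------------------------------------
# hydrogen bonds


def _pair_records(d_da, theta_deg):
    """An N-H donor and a carbonyl-O acceptor at controlled geometry:
    donor-acceptor distance ``d_da`` and D-H...A angle ``theta_deg``."""
    n = np.zeros(3)
    h = np.array([1.0, 0.0, 0.0])
    # unit vector H->A at the requested angle from H->N
    g = np.radians(180.0 - theta_deg)
    u = np.array([np.cos(g), np.sin(g), 0.0])
    # choose |H-A| = r so that |N-A| = d_da:  r^2 + 2 u_x r + 1 - d^2 = 0
    r = -u[0] + np.sqrt(u[0] ** 2 - 1.0 + d_da**2)
    a = h + r * u
    assert np.linalg.norm(a - n) == pytest.approx(d_da, abs=1e-9)
    donor = [
        AtomRecord("D1", "N", "N", n, 1.7, -0.47),
        AtomRecord("D1", "H", "H", h, 1.0, 0.31),
        AtomRecord("D1", "CA", "C", np.array([-1.0, 1.0, 0.0]), 1.9, 0.07),
    ]
    acc = [
        AtomRecord("A1", "O", "O", a, 1.6, -0.51),
        AtomRecord("A1", "C", "C", a + np.array([0.5, 1.1, 0.0]), 1.9, 0.51),
    ]
    return annotate_records(donor + acc)


def test_detect_hydrogen_bond_ideal_geometry():
    recs = _pair_records(2.9, 165.0)
    bonds = detect_hydrogen_bonds(recs)
    assert [(b.donor_id, b.acceptor_id) for b in bonds] == [(("D1", "N"), ("A1", "O"))]
    assert bonds[0].distance == pytest.approx(2.9, abs=1e-6)
    assert bonds[0].angle == pytest.approx(165.0, abs=1e-6)


@pytest.mark.parametrize(
    "d,theta,expected",
    [
        (4.0, 165.0, 0),   # too far
        (3.3, 165.0, 1),   # boundary distance: closed interval, detected
        (2.9, 100.0, 0),   # angle below the 120-degree gate
        (2.9, 120.0, 1),   # boundary angle included
    ],
)
def test_hbond_criterion_boundaries(d, theta, expected):
    assert len(detect_hydrogen_bonds(_pair_records(d, theta))) == expected


def test_hbond_recovery_fractions():
    ref = [(("A1", "N"), ("B1", "O")), (("A2", "N"), ("B1", "O"))]
    assert hbond_recovery(ref, ref)[0] == 1.0
    assert hbond_recovery([], ref)[0] == 0.0
    frac, matched, missed = hbond_recovery(ref[:1], ref)
    assert frac == 0.5 and len(matched) == 1 and len(missed) == 1
    # 80 of 88 recovered -> 0.909...
    big_ref = [((f"r{i}", "N"), ("TS", "O")) for i in range(88)]
    frac, _, _ = hbond_recovery(big_ref[:80], big_ref)
    assert frac == pytest.approx(80 / 88)
    with pytest.raises(ValueError):
        hbond_recovery(big_ref, [])


# ---------------------------------------------------------------------------
# energy tables on structures


def test_energy_table_symmetry_and_isolated_site(planted):
    fx = planted
    lib = expand_hydroxyl_rotamers(default_rotamer_library(), 120.0)
    ts_xyz = np.array(list(fx.truth.ts_pose.values()))
    sites = design_sites(fx.scaffold, ts_xyz, radius=7.0)
    table = build_energy_tables(fx.scaffold, fx.motif.ts, fx.truth.ts_pose, sites, lib)
    # pairwise symmetry through the accessor
    for (i, j), m in table.pairwise.items():
        assert np.allclose(table.pair(j, i), m.T)
    # interaction energy itself is symmetric in its arguments
    a = table.sites[0].records[0]
    env = ts_records(fx.motif.ts, fx.truth.ts_pose)
    assert interaction_energy(a, env) == pytest.approx(
        interaction_energy(env, a), abs=1e-9
    )


def test_clashing_rotamer_scores_worse_than_native(planted):
    """A rotamer whose side chain collides with the TS must receive a higher
    singleton energy than the planted (input) conformation."""
    fx = planted
    lib = expand_hydroxyl_rotamers(default_rotamer_library(), 120.0)
    ts_xyz = np.array(list(fx.truth.ts_pose.values()))
    sites = design_sites(fx.scaffold, ts_xyz, radius=7.0)
    his = next(s for s in sites if s.name == "HIS")
    table = build_energy_tables(fx.scaffold, fx.motif.ts, fx.truth.ts_pose, [his], lib)
    (site,) = table.sites
    energies = table.singleton[0]
    input_idx = next(i for i, r in enumerate(site.rotamers) if r.tag == "input")
    assert energies[input_idx] <= np.median(energies)


def test_binding_energy_properties(planted):
    from enzymatch.repacking import covalent_exclusions

    fx = planted
    prot = []
    for res in fx.scaffold.residues:
        prot.extend(residue_records(res, res.label, res.name))
    ts0 = ts_records(fx.motif.ts, fx.truth.ts_pose)
    excl = covalent_exclusions(fx.motif, fx.truth.assignment, fx.scaffold)
    e0 = binding_energy(prot, ts0, excluded_pairs=excl)
    # planted interface is attractive once the covalent junction is excluded
    assert e0 < 0
    # rigid translation of the TS far away -> zero interaction
    far_pose = {k: v + 100.0 for k, v in fx.truth.ts_pose.items()}
    assert binding_energy(prot, ts_records(fx.motif.ts, far_pose),
                          excluded_pairs=excl) == pytest.approx(0.0)
    # invariance under a global rigid transform of the whole complex
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=4).as_matrix()
    t = np.array([5.0, -3.0, 2.0])

    def move(recs):
        out = []
        for r in recs:
            out.append(AtomRecord(r.unit, r.name, r.element, R @ r.coords + t,
                                  r.radius, r.charge))
        return annotate_records(out)

    e_moved = binding_energy(move(prot), move(ts0), excluded_pairs=excl)
    assert e_moved == pytest.approx(e0, abs=1e-9)


def test_added_hbond_lowers_binding_energy():
    """Placing an ideal donor against a TS acceptor lowers the interaction."""
    from enzymatch.fixtures import toy_ts_model

    ts = toy_ts_model()
    pose = ts.reference_coords()
    o1 = pose["O1"]
    c1 = pose["C1"]
    u = o1 - c1
    u = u / np.linalg.norm(u)
    h = o1 + 1.9 * u
    n = o1 + 2.9 * u
    donor = annotate_records(
        [
            AtomRecord("res", "N", "N", n, 1.7, -0.47),
            AtomRecord("res", "H", "H", h, 1.0, 0.31),
        ]
    )
    no_donor = annotate_records(
        [AtomRecord("res", "CB", "C", n, 1.9, 0.0)]
    )
    e_with = binding_energy(donor, ts_records(ts, pose))
    e_without = binding_energy(no_donor, ts_records(ts, pose))
    assert e_with < e_without


def test_planted_hbond_recovery_with_fixed_ts(matched_pool):
    """Repacking with the TS fixed at the planted pose recovers the planted
    hydrogen-bond network."""
    from enzymatch.repacking import repack_active_site
    from enzymatch.motif import attachment_block

    total_ref = total_rec = 0
    for fx, _matches in matched_pool:
        blk = attachment_block(fx.motif, "SER1")
        ser = fx.truth.assignment["SER1"]
        result = repack_active_site(
            fx.scaffold, fx.motif.ts, fx.truth.ts_pose, fixed_sites=[ser],
        )
        pred = [(h.donor_id, h.acceptor_id) for h in result.hydrogen_bonds]
        frac, _, missed = hbond_recovery(pred, fx.truth.hydrogen_bonds)
        total_ref += len(fx.truth.hydrogen_bonds)
        total_rec += len(fx.truth.hydrogen_bonds) - len(missed)
    assert total_rec / total_ref >= 0.9


def test_total_energy_bitwise_reproducible(planted):
    from enzymatch.repacking import repack_active_site

    ser = planted.truth.assignment["SER1"]
    r1 = repack_active_site(planted.scaffold, planted.motif.ts, planted.truth.ts_pose,
                            fixed_sites=[ser])
    r2 = repack_active_site(planted.scaffold, planted.motif.ts, planted.truth.ts_pose,
                            fixed_sites=[ser])
    assert r1.total_energy == r2.total_energy
    assert r1.binding_energy == r2.binding_energy
    assert np.isfinite(r1.total_energy)
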