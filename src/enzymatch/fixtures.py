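"""Synthetic planted-active-site fixtures.

Generates compact toy scaffolds containing a planted, constraint-satisfying
active site: a rigid tetrahedral-intermediate-like transition state (TS),
a Ser-His-Asp catalytic triad covalently/hydrogen-bond coupled to it, two
backbone oxyanion-hole donors and one backbone donor stabilizing the
aspartate, surrounded by decoy residues.  The planted ground truth satisfies
every motif constraint exactly (bounded torsions at their optima, free
torsions on the sampling grid), so the full matching pipeline can be
validated without downloading any real structure.

Scaffold geometry is idealized: residues are placed as rigid units without
peptide connectivity or Ramachandran realism, which is irrelevant for the
matching problem (anchors are rigid backbone frames).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import templates
from .closure import ClosedLoop
from .geometry import wrap_degrees
from .loops import SideLoopSpec, build_main_loop, main_loop_roles
from .motif import (
    CatalyticMotif,
    GeometricConstraint,
    MotifResidue,
    check_match_constraints,
)
from .structure import ProteinStructure, Residue, TSModel

__all__ = [
    "PlantedFixture",
    "toy_ts_model",
    "toy_triad_motif",
    "generate_fixture",
    "perturb_fixture",
]


def toy_ts_model() -> TSModel:
    """A rigid 6-atom tetrahedral-intermediate mimic.

    C1 is the sp3 center; OX is the (serine-derived) nucleophile oxygen, part
    of the TS because the forming O-C bond belongs to the reaction center; O1
    is the oxyanion (hydrogen-bond acceptor target); OL/CL a truncated leaving
    group; CM a methyl substituent.
    """
    import yaml as _yaml

    doc = {
        "name": "tetrahedral_toy",
        "charge_set": "charmm",
        "atoms": [
            {"name": "OX", "element": "O", "charge": -0.40},
            {"name": "C1", "element": "C", "charge": 0.60},
            {"name": "O1", "element": "O", "charge": -0.90},
            {"name": "CM", "element": "C", "charge": 0.00},
            {"name": "OL", "element": "O", "charge": -0.40},
            {"name": "CL", "element": "C", "charge": 0.10},
        ],
        "zmatrix": [
            {"atom": "OX"},
            {"atom": "C1", "length": 1.50},
            {"atom": "O1", "length": 1.30, "angle": 109.5},
            {"atom": "CM", "frame": ["O1", "OX", "C1"], "length": 1.52,
             "angle": 109.5, "torsion": 120.0},
            {"atom": "OL", "frame": ["O1", "OX", "C1"], "length": 1.45,
             "angle": 109.5, "torsion": -120.0},
            {"atom": "CL", "frame": ["OX", "C1", "OL"], "length": 1.43,
             "angle": 117.0, "torsion": 180.0},
        ],
        "rotatable": [],
    }
    return TSModel.from_yaml(_yaml.safe_dump(doc))


def toy_triad_motif() -> CatalyticMotif:
    """Ser-His-Asp triad + oxyanion hole complex active-site model (toy TS).

    SER1/HIS2/ASP3 are the catalytic roles (the minimal model); ALA4/ALA5
    donate backbone hydrogen bonds to the oxyanion and ALA6 stabilizes the
    aspartate — the complex-model additions.
    """
    ts = toy_ts_model()
    S, H, D = "SER1", "HIS2", "ASP3"
    res = [
        MotifResidue(S, ("SER",), "catalytic", "side_chain", ("CB", "CA", "N")),
        MotifResidue(H, ("HIS",), "catalytic", "side_chain", ("NE2", "CE1", "ND1")),
        MotifResidue(D, ("ASP",), "catalytic", "side_chain", ("OD1", "CG", "CB")),
        MotifResidue("ALA4", ("ANY",), "stabilizes_TS", "backbone", ("H", "N", "CA")),
        MotifResidue("ALA5", ("ANY",), "stabilizes_TS", "backbone", ("H", "N", "CA")),
        MotifResidue("ALA6", ("ANY",), "stabilizes_catalytic", "backbone", ("H", "N", "CA")),
    ]
    C = GeometricConstraint
    cons = [
        # serine nucleophile: CB bonded to the TS oxygen OX
        C("distance", ((S, "CB"), ("TS", "OX")), 1.417, 0.10),
        C("angle", ((S, "CA"), (S, "CB"), ("TS", "OX")), 110.7, 8.0),
        C("angle", ((S, "CB"), ("TS", "OX"), ("TS", "C1")), 115.0, 20.0),
        C("improper_dihedral", ((S, "CB"), ("TS", "OX"), ("TS", "C1"), ("TS", "O1")), -60.0, 45.0),
        # histidine general base: NE2 against the nucleophile oxygen
        C("distance", ((H, "NE2"), ("TS", "OX")), 2.80, 0.20),
        C("angle", ((H, "CE1"), (H, "NE2"), ("TS", "OX")), 127.0, 15.0),
        C("angle", ((H, "NE2"), ("TS", "OX"), ("TS", "C1")), 109.0, 25.0),
        C("improper_dihedral", ((H, "NE2"), ("TS", "OX"), ("TS", "C1"), ("TS", "O1")), 150.0, 60.0),
        C("improper_dihedral", ((H, "CE1"), (H, "NE2"), ("TS", "OX"), ("TS", "C1")), 100.0, 70.0),
        C("improper_dihedral", ((H, "ND1"), (H, "CE1"), (H, "NE2"), ("TS", "OX")), 180.0, 30.0),
        # aspartate orienting the histidine (ND1-H donor)
        C("distance", ((D, "OD1"), (H, "ND1")), 2.80, 0.20),
        C("angle", ((D, "CG"), (D, "OD1"), (H, "ND1")), 120.0, 30.0),
        C("angle", ((D, "OD1"), (H, "ND1"), (H, "CE1")), 126.0, 25.0),
        C("improper_dihedral", ((D, "OD1"), (H, "ND1"), (H, "CE1"), (H, "NE2")), 180.0, 25.0),
        C("improper_dihedral", ((D, "CB"), (D, "CG"), (D, "OD1"), (H, "ND1")), 180.0, 60.0),
        # oxyanion hole: two backbone amide donors flanking the oxyanion
        C("distance", (("ALA4", "H"), ("TS", "O1")), 1.95, 0.25),
        C("angle", (("ALA4", "N"), ("ALA4", "H"), ("TS", "O1")), 160.0, 20.0),
        C("angle", (("ALA4", "H"), ("TS", "O1"), ("TS", "C1")), 120.0, 40.0),
        C("improper_dihedral", (("ALA4", "H"), ("TS", "O1"), ("TS", "C1"), ("TS", "OX")), 150.0, 60.0),
        C("distance", (("ALA5", "H"), ("TS", "O1")), 2.10, 0.25),
        C("angle", (("ALA5", "N"), ("ALA5", "H"), ("TS", "O1")), 155.0, 20.0),
        C("angle", (("ALA5", "H"), ("TS", "O1"), ("TS", "C1")), 115.0, 40.0),
        C("improper_dihedral", (("ALA5", "H"), ("TS", "O1"), ("TS", "C1"), ("TS", "OX")), -90.0, 60.0),
        # backbone donor stabilizing the aspartate's second carboxylate oxygen
        C("distance", (("ALA6", "H"), (D, "OD2")), 1.95, 0.25),
        C("angle", (("ALA6", "N"), ("ALA6", "H"), (D, "OD2")), 160.0, 20.0),
        C("angle", (("ALA6", "H"), (D, "OD2"), (D, "CG")), 120.0, 40.0),
        C("improper_dihedral", (("ALA6", "H"), (D, "OD2"), (D, "CG"), (D, "OD1")), 180.0, 45.0),
    ]
    return CatalyticMotif("toy_triad_complex", res, ts, cons)


@dataclass
class GroundTruth:
    assignment: dict[str, tuple]
    ts_pose: dict[str, np.ndarray]
    conformations: dict[str, dict[str, np.ndarray]]
    hydrogen_bonds: list[tuple] = field(default_factory=list)
    torsions: dict[str, np.ndarray] = field(default_factory=dict)
    valid: bool = True


@dataclass
class PlantedFixture:
    scaffold: ProteinStructure
    motif: CatalyticMotif
    truth: GroundTruth
    seed: int
    catalytic_site_ids: list[tuple] = field(default_factory=list)


class InfeasibleMotifError(ValueError):
    pass


def _pick_free_torsions(chain, rng) -> np.ndarray:
    """Planted torsions: bounded at optimum, free drawn from the start grid."""
    x = np.empty(chain.n_var)
    for i, v in enumerate(chain.variables):
        if v.bounded:
            x[i] = v.seed
        else:
            g = v.grid()
            x[i] = g[rng.integers(len(g))]
    return x


def assemble_residue(
    aa: str, placed: dict[str, np.ndarray], drop: set[str] = frozenset()
) -> dict[str, np.ndarray]:
    """Full-atom residue from placed backbone + measured chi angles.

    ``drop`` removes atoms replaced by a covalent pseudo-bond partner (e.g.
    serine OG when the nucleophile oxygen belongs to the TS model), together
    with everything whose placement depends on them.
    """
    chis = templates.measure_chis(aa, placed)
    atoms = templates.build_residue(aa, placed["N"], placed["CA"], placed["C"], chis=chis)
    if drop:
        for name in templates.with_dependents(aa, set(drop)):
            atoms.pop(name, None)
    return atoms


def _random_rigid(rng) -> tuple[np.ndarray, np.ndarray]:
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31 - 1))).as_matrix()
    t = rng.uniform(-20.0, 20.0, size=3)
    return R, t


def generate_fixture(
    seed: int,
    motif: Optional[CatalyticMotif] = None,
    n_residues: int = 14,
    decoy_sites: int = 6,
    max_attempts: int = 20,
) -> PlantedFixture:
    """Generate a toy scaffold with a planted, exactly-satisfying active site.

    The planted site is built by running the matching kinematics *forward*:
    free torsions are drawn from the multistart grid, bounded torsions sit at
    their constraint optima, and the computed backbone frames become the
    scaffold anchors, so closure of the planted assignment is exact.  Decoy
    poly-alanine residues are scattered within the candidate radius without
    clashing.  Regeneration from the same seed is bit-identical.
    """
    motif = motif or toy_triad_motif()
    n_roles = len(motif.residues)
    if n_residues < n_roles + decoy_sites:
        raise ValueError("n_residues must cover motif roles plus decoys")
    rng = np.random.default_rng(seed)
    for attempt in range(max_attempts):
        fx = _try_generate(motif, rng, decoy_sites, seed)
        if fx is not None:
            return fx
    raise InfeasibleMotifError(
        f"could not generate a clash-free planted fixture in {max_attempts} attempts"
    )


def _clash(atoms_a: np.ndarray, atoms_b: np.ndarray, cutoff: float) -> bool:
    if len(atoms_a) == 0 or len(atoms_b) == 0:
        return False
    d2 = np.sum((atoms_a[:, None] - atoms_b[None]) ** 2, axis=-1)
    return bool(np.min(d2) < cutoff * cutoff)


def _try_generate(motif, rng, decoy_sites, seed) -> Optional[PlantedFixture]:
    r1, r2 = main_loop_roles(motif)
    ts = motif.ts

    # a scratch scaffold providing anchor-frame residues for chain building
    def _dummy_site(res_id, backbone):
        res = Residue(chain_id="A", number=res_id, name="ALA")
        for n, xyz in backbone.items():
            res.set_atom(n, xyz)
        return res

    seed_bb = {
        "N": np.array([1.458, 0.0, 0.0]),
        "CA": np.zeros(3),
        "C": np.array([0.53, 1.43, 0.0]),
    }
    site1 = _dummy_site(1, seed_bb)
    site2 = _dummy_site(2, seed_bb)  # target coords are irrelevant for forward runs
    scratch = ProteinStructure(residues=[site1, site2], source_id="scratch")
    main = build_main_loop(motif, scratch, r1, site1, r2, site2)
    x_main = _pick_free_torsions(main.chain, rng)
    coords = main.chain.forward(x_main)
    placed = ClosedLoop(x_main, 0.0, 0.0, coords, True).group_coords(main)

    # role 1 anchors at the seed backbone
    placed[r1].update(seed_bb)
    conformations: dict[str, dict[str, np.ndarray]] = {}
    torsions: dict[str, np.ndarray] = {r1 + "+" + r2: x_main}
    ts_pose = dict(placed["TS"])

    aa_of = {r.role_id: (r.allowed_aa[0] if "ANY" not in r.allowed_aa else "ALA")
             for r in motif.residues}

    def _covalent_drop(role_id, aa, grp):
        """Covalent pseudo-bond: alias the replaced heavy atom onto the
        partner position for chi measurement, and return atoms to drop."""
        from .motif import attachment_block

        block = attachment_block(motif, role_id)
        if block.distance[0] >= 1.8 or block.partner != "TS":
            return set()
        ext = templates.bonded_extension(aa, block.a_triple[0])
        if ext is None:
            return set()
        grp[ext] = ts_pose[block.b_triple[0]]
        return {ext}

    drop1 = _covalent_drop(r1, aa_of[r1], placed[r1])
    drop2 = _covalent_drop(r2, aa_of[r2], placed[r2])
    conformations[r1] = assemble_residue(aa_of[r1], placed[r1], drop=drop1)
    conformations[r2] = assemble_residue(aa_of[r2], placed[r2], drop=drop2)

    # side roles, built outward from their partners at constraint optima
    _, side_specs = _silent_side_specs(motif, r1, r2)
    partner_atoms: dict[str, dict[str, np.ndarray]] = {
        "TS": ts_pose, r1: conformations[r1], r2: conformations[r2]
    }
    for spec in side_specs:
        site = _dummy_site(99, seed_bb)
        loop = spec.bind(partner_atoms[spec.partner], site)
        x = _pick_free_torsions(loop.chain, rng)
        coords = loop.chain.forward(x)
        grp = ClosedLoop(x, 0.0, 0.0, coords, True).group_coords(loop)[spec.role_id]
        aa = aa_of[spec.role_id] if motif.role(spec.role_id).interaction_via == "side_chain" else "ALA"
        conformations[spec.role_id] = assemble_residue(aa, grp)
        partner_atoms[spec.role_id] = conformations[spec.role_id]
        torsions[spec.role_id] = x

    # clash screen among planted units (heavy atoms); pairs joined by a
    # covalent pseudo-bond are exempt (their contact is the bond itself)
    unit_keys = ["TS"] + list(conformations)
    units = [np.array([v for k, v in ts_pose.items()])]
    for role_id, atoms in conformations.items():
        units.append(np.array([v for k, v in atoms.items() if not k.startswith("H")]))
    covalent = {("TS", r1)} if drop1 else set()
    if drop2:
        covalent.add(("TS", r2))
    for i in range(len(units)):
        for j in range(i + 1, len(units)):
            if (unit_keys[i], unit_keys[j]) in covalent:
                continue
            if _clash(units[i], units[j], 2.2):
                return None

    # verify the planted geometry satisfies every constraint
    coords_map = {"TS": ts_pose, **conformations}
    report = check_match_constraints(motif, coords_map)
    if not report.all_satisfied:
        return None

    # scatter clash-free poly-alanine decoys around the pocket
    all_heavy = np.vstack(units)
    ts_centroid = np.mean([v for v in ts_pose.values()], axis=0)
    decoys = []
    tries = 0
    while len(decoys) < decoy_sites and tries < 400:
        tries += 1
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        dist = rng.uniform(7.5, 12.5)
        ca = ts_centroid + direction * dist
        R, _ = _random_rigid(rng)
        n = ca + R @ np.array([1.458, 0.0, 0.0])
        c = ca + R @ np.array([0.53, 1.43, 0.0])
        atoms = templates.build_residue("ALA", n, ca, c)
        heavy = np.array([v for k, v in atoms.items() if not k.startswith("H")])
        if _clash(heavy, all_heavy, 4.0):
            continue
        if decoys and _clash(heavy, np.vstack(decoys), 4.0):
            continue
        decoys.append(heavy)

    if len(decoys) < decoy_sites:
        return None

    # apply one global rigid transform so fixtures are not axis-aligned
    R, t = _random_rigid(rng)

    def _tx(x):
        return R @ np.asarray(x) + t

    site_units: list[tuple[Optional[str], Optional[dict[str, np.ndarray]]]] = [
        (role_id, conformations[role_id]) for role_id in conformations
    ] + [(None, None)] * len(decoys)
    order = rng.permutation(len(site_units))
    return _finalize_fixture(
        motif, seed, order, site_units, decoys, ts_pose, torsions, _tx, aa_of
    )


def _finalize_fixture(
    motif, seed, order, site_units, decoy_atoms_list, ts_pose, torsions, _tx, aa_of
):
    residues = []
    assignment = {}
    di = 0
    conf_tx: dict[str, dict[str, np.ndarray]] = {}
    for num, k in enumerate(order, start=1):
        role_id, atoms = site_units[k]
        res = Residue(chain_id="A", number=int(num), name="ALA")
        if role_id is None:
            heavy = decoy_atoms_list[di]
            di += 1
            full = templates.build_residue(
                "ALA", _tx(heavy[0]), _tx(heavy[1]), _tx(heavy[2])
            )
            for name, xyz in full.items():
                res.set_atom(name, xyz)
        else:
            role = motif.role(role_id)
            res.name = aa_of[role_id] if role.interaction_via == "side_chain" else "ALA"
            conf_tx[role_id] = {name: _tx(xyz) for name, xyz in atoms.items()}
            for name, xyz in conf_tx[role_id].items():
                res.set_atom(name, xyz)
            assignment[role_id] = res.res_id
        residues.append(res)
    scaffold = ProteinStructure(residues=residues, source_id=f"fixture{seed}")
    scaffold.hydrogens_built = True
    ts_tx = {name: _tx(xyz) for name, xyz in ts_pose.items()}

    from .repacking import detect_hydrogen_bonds, site_atom_records

    records = site_atom_records(scaffold, ts_model=motif.ts, ts_pose=ts_tx)
    hbonds = [
        (hb.donor_id, hb.acceptor_id) for hb in detect_hydrogen_bonds(records)
    ]
    truth = GroundTruth(
        assignment=assignment,
        ts_pose=ts_tx,
        conformations=conf_tx,
        hydrogen_bonds=hbonds,
        torsions=torsions,
        valid=True,
    )
    catalytic_ids = [assignment[r.role_id] for r in motif.catalytic_roles()]
    return PlantedFixture(
        scaffold=scaffold, motif=motif, truth=truth, seed=seed,
        catalytic_site_ids=catalytic_ids,
    )


def _silent_side_specs(motif, r1, r2):
    from .motif import attachment_block

    sides = []
    placed = {"TS", r1, r2}
    for role in motif.residues:
        if role.role_id in (r1, r2):
            continue
        block = attachment_block(motif, role.role_id)
        if block.partner not in placed:
            raise ValueError(f"side role {role.role_id} partner {block.partner} not placed")
        sides.append(SideLoopSpec(motif, role.role_id, block))
        placed.add(role.role_id)
    return None, sides


def perturb_fixture(fixture: PlantedFixture, torsion_noise: float, seed: int) -> PlantedFixture:
    """Copy a fixture with side-chain chi angles of the planted residues
    perturbed by uniform noise; the truth is revalidated and flagged invalid
    if any constraint now exceeds its tolerance."""
    if torsion_noise < 0:
        raise ValueError("torsion_noise must be >= 0")
    rng = np.random.default_rng(seed)
    new_conf: dict[str, dict[str, np.ndarray]] = {}
    scaffold = fixture.scaffold
    residues = []
    for res in scaffold.residues:
        clone = Residue(res.chain_id, res.number, res.name, res.icode)
        for n, a in res.atoms.items():
            clone.set_atom(n, a.coords.copy(), element=a.element)
        residues.append(clone)
    new_scaffold = ProteinStructure(residues=residues, source_id=scaffold.source_id)
    new_scaffold.hydrogens_built = scaffold.hydrogens_built

    for role in fixture.motif.residues:
        rid = fixture.truth.assignment[role.role_id]
        res = new_scaffold.get(rid)
        atoms = fixture.truth.conformations[role.role_id]
        if role.interaction_via == "side_chain" and torsion_noise > 0:
            aa = res.name
            chis = templates.measure_chis(aa, atoms)
            noisy = [wrap_degrees(c + rng.uniform(-torsion_noise, torsion_noise)) for c in chis]
            rebuilt = templates.build_residue(aa, atoms["N"], atoms["CA"], atoms["C"], chis=noisy)
            for n, xyz in rebuilt.items():
                res.set_atom(n, xyz)
            new_conf[role.role_id] = rebuilt
        else:
            new_conf[role.role_id] = {k: v.copy() for k, v in atoms.items()}
    coords_map = {"TS": fixture.truth.ts_pose, **new_conf}
    report = check_match_constraints(fixture.motif, coords_map)
    truth = GroundTruth(
        assignment=dict(fixture.truth.assignment),
        ts_pose={k: v.copy() for k, v in fixture.truth.ts_pose.items()},
        conformations=new_conf,
        hydrogen_bonds=list(fixture.truth.hydrogen_bonds),
        torsions={k: v.copy() for k, v in fixture.truth.torsions.items()},
        valid=report.all_satisfied,
    )
    return PlantedFixture(
        scaffold=new_scaffold, motif=fixture.motif, truth=truth,
        seed=fixture.seed, catalytic_site_ids=list(fixture.catalytic_site_ids),
    )
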