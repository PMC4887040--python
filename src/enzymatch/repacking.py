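"""Rotamer-based side-chain repacking around a fixed transition state.

Residues within the design shell (default 7 A of the TS, excluding prolines)
are repacked: each site's candidate conformations come from a
backbone-independent rotamer library (augmented with the input side-chain
conformation), Ser/Thr/Tyr/Cys hydroxyl hydrogens are expanded on a torsion
grid, singleton/pairwise energy tables are built with the package energy
model, dead-end elimination (Goldstein) provably shrinks the tables, and the
global minimum-energy conformation (GMEC) is found exactly — by exhaustive
enumeration for small problems, by mixed-integer linear programming (HiGHS)
otherwise.

The binding energy of the repacked complex is the energy difference between
the bound and rigidly separated enzyme-TS systems, which for a pairwise
model equals the protein-TS interaction energy at the repacked conformation.
"""

from __future__ import annotations

import importlib.resources
import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import params as _params
from . import templates
from .energy import (
    AtomRecord,
    AtomRecords,
    DEFAULT_ENERGY_PARAMS,
    EnergyParams,
    HBond,
    annotate_records,
    detect_hydrogen_bonds,
    interaction_energy,
)
from .structure import ProteinStructure, Residue, TSModel, design_sites

__all__ = [
    "Rotamer",
    "RotamerLibrary",
    "load_rotamer_library",
    "default_rotamer_library",
    "expand_hydroxyl_rotamers",
    "EnergyTable",
    "build_energy_tables",
    "dee_reduce",
    "solve_gmec",
    "RepackResult",
    "repack_active_site",
    "binding_energy",
    "hbond_recovery",
    "detect_hydrogen_bonds",
    "residue_records",
    "ts_records",
    "site_atom_records",
]

logger = logging.getLogger(__name__)

_BACKBONE = {"N", "CA", "C", "O", "H", "HA", "HA1", "HA2", "OXT"}


@dataclass(frozen=True)
class Rotamer:
    chis: tuple[float, ...]
    hydroxyl: Optional[float] = None
    tag: str = "lib"


@dataclass
class RotamerLibrary:
    """Per-residue chi-angle vectors; backbone independent."""

    rotamers: dict[str, list[Rotamer]]
    provenance: str = "builtin"

    def for_aa(self, aa: str) -> list[Rotamer]:
        return self.rotamers.get(aa.upper(), [])

    def n_rotamers(self) -> int:
        return sum(len(v) for v in self.rotamers.values())


def load_rotamer_library(text: str, provenance: str = "file") -> RotamerLibrary:
    rot: dict[str, list[Rotamer]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        aa = parts[0].upper()
        chis = tuple(float(x) for x in parts[1:])
        expected = templates.N_CHI.get(aa)
        if expected is not None and len(chis) != expected:
            raise ValueError(f"{aa} rotamer needs {expected} chi values, got {len(chis)}")
        rot.setdefault(aa, []).append(Rotamer(chis))
    return RotamerLibrary(rot, provenance)


def default_rotamer_library() -> RotamerLibrary:
    text = (
        importlib.resources.files("enzymatch").joinpath("data/rotamers.txt").read_text()
    )
    return load_rotamer_library(text, provenance="builtin")


def expand_hydroxyl_rotamers(library: RotamerLibrary, step: float = 120.0) -> RotamerLibrary:
    """Replicate Ser/Thr/Tyr/Cys rotamers over a hydroxyl-hydrogen torsion grid.

    The hydroxyl (or thiol) hydrogen can adopt multiple positions at fixed
    heavy-atom geometry, which matters for hydrogen-bond scoring.  ``step``
    must divide 360.
    """
    if step <= 0 or abs(360.0 / step - round(360.0 / step)) > 1e-9:
        raise ValueError("step must divide 360")
    n = int(round(360.0 / step))
    out: dict[str, list[Rotamer]] = {}
    for aa, rots in library.rotamers.items():
        if aa in templates.HYDROXYL_H:
            out[aa] = [
                Rotamer(r.chis, hydroxyl=float(-180.0 + step * k), tag=r.tag)
                for r in rots
                for k in range(n)
            ]
        else:
            out[aa] = list(rots)
    return RotamerLibrary(out, provenance=f"{library.provenance}+hydroxyl{int(step)}")


# ---------------------------------------------------------------------------
# Atom records


def residue_records(
    res_or_atoms,
    unit: str,
    resname: str,
    subset: Optional[str] = None,  # None | "backbone" | "sidechain"
) -> list[AtomRecord]:
    """Scoring records for a residue (Residue object or atom-name dict)."""
    if isinstance(res_or_atoms, Residue):
        items = [(n, a.coords) for n, a in res_or_atoms.atoms.items()]
    else:
        items = list(res_or_atoms.items())
    out = []
    for name, coords in items:
        bb = name in _BACKBONE
        if subset == "backbone" and not bb:
            continue
        if subset == "sidechain" and bb:
            continue
        el = _params.element_from_name(name)
        out.append(
            AtomRecord(
                unit=unit,
                name=name,
                element=el,
                coords=np.asarray(coords, float),
                radius=_params.vdw_radius(el),
                charge=_params.partial_charge(resname, name),
            )
        )
    return annotate_records(out)


def ts_records(ts_model: TSModel, ts_pose: dict[str, np.ndarray]) -> list[AtomRecord]:
    out = []
    for atom in ts_model.atoms:
        if atom.name not in ts_pose:
            continue
        out.append(
            AtomRecord(
                unit="TS",
                name=atom.name,
                element=atom.element,
                coords=np.asarray(ts_pose[atom.name], float),
                radius=atom.vdw_radius,
                charge=atom.partial_charge or 0.0,
            )
        )
    return annotate_records(out)


def site_atom_records(
    scaffold: ProteinStructure,
    ts_model: Optional[TSModel] = None,
    ts_pose: Optional[dict] = None,
    residues: Optional[Iterable[Residue]] = None,
    assignment_atoms: Optional[dict] = None,
) -> list[AtomRecord]:
    """Records for scaffold residues (optionally overridden per unit) + TS."""
    out: list[AtomRecord] = []
    for res in residues if residues is not None else scaffold.residues:
        out.extend(residue_records(res, res.label, res.name))
    if assignment_atoms:
        for unit, atoms in assignment_atoms.items():
            out.extend(residue_records(atoms, unit, unit))
    if ts_model is not None and ts_pose is not None:
        out.extend(ts_records(ts_model, ts_pose))
    return out


def place_rotamer(res: Residue, rot: Rotamer, aa: Optional[str] = None) -> dict[str, np.ndarray]:
    """Side-chain atoms (heavy + hydrogens) of a rotamer on a site's backbone."""
    aa = aa or res.name
    atoms = templates.build_residue(
        aa, res.coord("N"), res.coord("CA"), res.coord("C"),
        chis=rot.chis, hydroxyl=rot.hydroxyl,
        include_backbone_extras=False,
    )
    return {n: c for n, c in atoms.items() if n not in _BACKBONE}


# ---------------------------------------------------------------------------
# Energy tables


@dataclass
class SiteRotamers:
    res_id: tuple
    label: str
    aa: str
    rotamers: list[Rotamer]
    records: list[AtomRecords]  # side-chain records per rotamer


@dataclass
class EnergyTable:
    sites: list[SiteRotamers]
    singleton: list[np.ndarray]  # [n_rot_i] per site
    pairwise: dict[tuple[int, int], np.ndarray]  # (i, j) i<j -> (n_i, n_j)

    def n_combinations(self) -> int:
        n = 1
        for s in self.sites:
            n *= max(1, len(s.rotamers))
        return n

    def pair(self, i: int, j: int) -> np.ndarray:
        if i < j:
            return self.pairwise.get((i, j), np.zeros((len(self.sites[i].rotamers),
                                                       len(self.sites[j].rotamers))))
        return self.pair(j, i).T

    def assignment_energy(self, assignment: Sequence[int]) -> float:
        e = sum(float(self.singleton[i][r]) for i, r in enumerate(assignment))
        for (i, j), m in self.pairwise.items():
            e += float(m[assignment[i], assignment[j]])
        return e


def build_energy_tables(
    scaffold: ProteinStructure,
    ts_model: TSModel,
    ts_pose: dict[str, np.ndarray],
    sites: Sequence[Residue],
    library: RotamerLibrary,
    include_current: bool = True,
    fixed_sites: Sequence[tuple] = (),
    excluded_pairs: Optional[Iterable[tuple]] = None,
    energy_params: EnergyParams = DEFAULT_ENERGY_PARAMS,
    pair_cutoff: float = 10.0,
) -> EnergyTable:
    """Singleton and pairwise rotamer energies for the design sites.

    Singleton = rotamer side chain vs the fixed environment (template
    residues, all design-site backbones, side chains of fixed sites, TS).
    ``include_current`` augments each site with its input conformation.
    """
    fixed = set(tuple(f) for f in fixed_sites)
    design = [r for r in sites if r.res_id not in fixed]
    design_ids = {r.res_id for r in design}

    env_records: list[AtomRecord] = []
    for res in scaffold.residues:
        if res.res_id in design_ids:
            env_records.extend(residue_records(res, res.label, res.name, subset="backbone"))
        else:
            env_records.extend(residue_records(res, res.label, res.name))
    env_records.extend(ts_records(ts_model, ts_pose))
    env = AtomRecords(env_records)

    table_sites: list[SiteRotamers] = []
    for res in design:
        rots: list[Rotamer] = []
        if include_current and templates.N_CHI.get(res.name, 0) > 0:
            chis = templates.measure_chis(res.name, res.coords_dict())
            rots.append(Rotamer(tuple(chis), tag="input"))
        rots.extend(library.for_aa(res.name))
        if not rots:
            rots = [Rotamer((), tag="fixed")]
        recs = []
        ok_rots = []
        for rot in rots:
            try:
                atoms = place_rotamer(res, rot)
            except Exception as exc:  # pragma: no cover - placement failure
                logger.warning("dropping rotamer %s at %s: %s", rot, res.label, exc)
                continue
            recs.append(AtomRecords(residue_records(atoms, res.label, res.name)))
            ok_rots.append(rot)
        table_sites.append(SiteRotamers(res.res_id, res.label, res.name, ok_rots, recs))

    singleton = []
    for s in table_sites:
        e = np.array(
            [
                interaction_energy(r, env, energy_params, excluded_pairs=excluded_pairs)
                for r in s.records
            ]
        )
        singleton.append(e)

    pairwise: dict[tuple[int, int], np.ndarray] = {}
    cas = [scaffold.get(s.res_id).coord("CA") for s in table_sites]
    for i in range(len(table_sites)):
        for j in range(i + 1, len(table_sites)):
            if float(np.linalg.norm(cas[i] - cas[j])) > pair_cutoff + 6.0:
                continue
            si, sj = table_sites[i], table_sites[j]
            m = np.zeros((len(si.rotamers), len(sj.rotamers)))
            for a, ra in enumerate(si.records):
                for b, rb in enumerate(sj.records):
                    m[a, b] = interaction_energy(ra, rb, energy_params,
                                                 excluded_pairs=excluded_pairs)
            if np.any(m != 0.0):
                pairwise[(i, j)] = m
    return EnergyTable(table_sites, singleton, pairwise)


# ---------------------------------------------------------------------------
# DEE / GMEC


def dee_reduce(table: EnergyTable, max_rounds: int = 50) -> EnergyTable:
    """Goldstein dead-end elimination iterated to a fixed point.

    A rotamer r at site i is eliminated when some alternative t satisfies
    E_i(r) - E_i(t) + sum_j min_s [E_ij(r,s) - E_ij(t,s)] > 0; eliminated
    rotamers provably cannot occur in the GMEC.
    """
    alive = [np.ones(len(s.rotamers), dtype=bool) for s in table.sites]
    n_sites = len(table.sites)
    for _ in range(max_rounds):
        changed = False
        for i in range(n_sites):
            live_i = np.where(alive[i])[0]
            if len(live_i) <= 1:
                continue
            for r in live_i:
                for t in live_i:
                    if t == r:
                        continue
                    gap = table.singleton[i][r] - table.singleton[i][t]
                    for j in range(n_sites):
                        if j == i:
                            continue
                        m = table.pair(i, j)
                        live_j = np.where(alive[j])[0]
                        if len(live_j) == 0:
                            raise ValueError(f"site {table.sites[j].label} fully eliminated")
                        gap += float(np.min(m[r, live_j] - m[t, live_j]))
                    if gap > 1e-12:
                        alive[i][r] = False
                        changed = True
                        break
        if not changed:
            break
    for i, a in enumerate(alive):
        if not a.any():
            raise ValueError(f"site {table.sites[i].label} fully eliminated (inconsistent model)")
    new_sites = []
    new_singleton = []
    index_maps = []
    for i, s in enumerate(table.sites):
        keep = np.where(alive[i])[0]
        index_maps.append(keep)
        new_sites.append(
            SiteRotamers(
                s.res_id, s.label, s.aa,
                [s.rotamers[k] for k in keep],
                [s.records[k] for k in keep] if s.records else [],
            )
        )
        new_singleton.append(table.singleton[i][keep])
    new_pairwise = {}
    for (i, j), m in table.pairwise.items():
        new_pairwise[(i, j)] = m[np.ix_(index_maps[i], index_maps[j])]
    return EnergyTable(new_sites, new_singleton, new_pairwise)


def _solve_exhaustive(table: EnergyTable) -> tuple[list[int], float]:
    sizes = [len(s.rotamers) for s in table.sites]
    best, best_e = None, np.inf
    for combo in itertools.product(*(range(n) for n in sizes)):
        e = table.assignment_energy(combo)
        if e < best_e - 1e-12:
            best, best_e = list(combo), e
    return best, float(best_e)


def _solve_milp(table: EnergyTable) -> tuple[list[int], float]:
    from scipy import sparse
    from scipy.optimize import LinearConstraint, milp

    sizes = [len(s.rotamers) for s in table.sites]
    x_off = np.cumsum([0] + sizes)
    nx = int(x_off[-1])
    pair_keys = sorted(table.pairwise)
    y_off = {}
    ny = 0
    for key in pair_keys:
        y_off[key] = nx + ny
        ny += sizes[key[0]] * sizes[key[1]]
    nvar = nx + ny

    c = np.zeros(nvar)
    for i, e in enumerate(table.singleton):
        c[x_off[i]:x_off[i] + sizes[i]] = e
    for key in pair_keys:
        i, j = key
        c[y_off[key]:y_off[key] + sizes[i] * sizes[j]] = table.pairwise[key].ravel()

    rows, cols, vals, lb, ub = [], [], [], [], []
    row = 0
    for i in range(len(sizes)):  # sum_r x_ir = 1
        for r in range(sizes[i]):
            rows.append(row); cols.append(x_off[i] + r); vals.append(1.0)
        lb.append(1.0); ub.append(1.0); row += 1
    for key in pair_keys:
        i, j = key
        for r in range(sizes[i]):  # sum_s y = x_ir
            for s in range(sizes[j]):
                rows.append(row); cols.append(y_off[key] + r * sizes[j] + s); vals.append(1.0)
            rows.append(row); cols.append(x_off[i] + r); vals.append(-1.0)
            lb.append(0.0); ub.append(0.0); row += 1
        for s in range(sizes[j]):  # sum_r y = x_js
            for r in range(sizes[i]):
                rows.append(row); cols.append(y_off[key] + r * sizes[j] + s); vals.append(1.0)
            rows.append(row); cols.append(x_off[j] + s); vals.append(-1.0)
            lb.append(0.0); ub.append(0.0); row += 1
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(row, nvar))
    integrality = np.zeros(nvar)
    integrality[:nx] = 1  # x binary; y continuous (tight given the flow constraints)
    from scipy.optimize import Bounds

    res = milp(
        c,
        constraints=LinearConstraint(A, np.array(lb), np.array(ub)),
        integrality=integrality,
        bounds=Bounds(0, 1),
    )
    if not res.success:
        raise RuntimeError(f"MILP solver failed: {res.message}")
    assignment = []
    for i in range(len(sizes)):
        xi = res.x[x_off[i]:x_off[i] + sizes[i]]
        assignment.append(int(np.argmax(xi)))
    return assignment, float(table.assignment_energy(assignment))


def solve_gmec(table: EnergyTable, exhaustive_limit: int = 10**6) -> tuple[list[int], float]:
    """Exact global minimum-energy rotamer assignment.

    Exhaustive enumeration when the combination count is small; otherwise a
    mixed-integer linear program (with exhaustive fallback on solver failure
    when feasible).
    """
    if not table.sites:
        return [], 0.0
    if table.n_combinations() <= exhaustive_limit:
        return _solve_exhaustive(table)
    try:
        return _solve_milp(table)
    except RuntimeError:
        logger.warning("MILP failed; attempting exhaustive fallback")
        return _solve_exhaustive(table)


def covalent_exclusions(motif, assignment: dict[str, tuple], scaffold=None) -> list[tuple]:
    """Non-bonded exclusion pairs across covalent pseudo-bonds to the TS.

    For every motif role attached to the TS by a sub-1.8-A distance constraint
    (a forming/formed covalent bond), residue atoms within two bonds of the
    attachment atom are excluded against TS atoms within two bonds of the
    partner atom (1-2 through 1-4 interactions across the junction).
    """
    from .motif import attachment_block

    pairs: list[tuple] = []
    for role in motif.residues:
        if role.interaction_via != "side_chain":
            continue
        block = attachment_block(motif, role.role_id)
        if block.partner != "TS" or block.distance[0] >= 1.8:
            continue
        rid = assignment.get(role.role_id)
        if rid is None:
            continue
        label = f"{rid[0]}{rid[1]}{rid[2]}"
        aa = role.allowed_aa[0] if "ANY" not in role.allowed_aa else None
        if aa is None and scaffold is not None:
            aa = scaffold.get(rid).name
        if aa is None:
            continue
        res_nbrs = templates.residue_bond_graph(aa)
        res_d = templates.bond_distance(res_nbrs, block.a_triple[0], max_depth=2)
        ts_nbrs: dict[str, set] = {}
        for x, y in motif.ts.bonds():
            ts_nbrs.setdefault(x, set()).add(y)
            ts_nbrs.setdefault(y, set()).add(x)
        ts_d = templates.bond_distance(ts_nbrs, block.b_triple[0], max_depth=2)
        for a_name, da in res_d.items():
            for b_name, db in ts_d.items():
                if da + db <= 2:
                    pairs.append(((label, a_name), ("TS", b_name)))
    return pairs


# ---------------------------------------------------------------------------
# Repacking driver


@dataclass
class RepackResult:
    assignment: dict[tuple, Rotamer]
    total_energy: float
    hydrogen_bonds: list[HBond]
    binding_energy: float
    design_site_ids: list[tuple] = field(default_factory=list)
    repacked: Optional[ProteinStructure] = None


def binding_energy(
    protein_records,
    ts_recs,
    energy_params: EnergyParams = DEFAULT_ENERGY_PARAMS,
    excluded_pairs: Optional[Iterable[tuple]] = None,
) -> float:
    """E(complex) - E(protein) - E(TS) under rigid separation.

    Intramolecular terms cancel exactly, leaving the protein-TS interaction
    energy at the repacked conformation.
    """
    return interaction_energy(protein_records, ts_recs, energy_params,
                              excluded_pairs=excluded_pairs)


def repack_active_site(
    scaffold: ProteinStructure,
    ts_model: TSModel,
    ts_pose: dict[str, np.ndarray],
    radius: float = 7.0,
    library: Optional[RotamerLibrary] = None,
    hydroxyl_step: float = 120.0,
    fixed_sites: Sequence[tuple] = (),
    excluded_pairs: Optional[Iterable[tuple]] = None,
    energy_params: EnergyParams = DEFAULT_ENERGY_PARAMS,
) -> RepackResult:
    """Repack the design shell around a fixed TS pose and score the result."""
    if library is None:
        library = expand_hydroxyl_rotamers(default_rotamer_library(), hydroxyl_step)
    ts_xyz = np.array([ts_pose[n] for n in ts_model.heavy_names() if n in ts_pose])
    sites = design_sites(scaffold, ts_xyz, radius=radius)
    table = build_energy_tables(
        scaffold, ts_model, ts_pose, sites, library,
        fixed_sites=fixed_sites, excluded_pairs=excluded_pairs,
        energy_params=energy_params,
    )
    reduced = dee_reduce(table)
    assignment, total = solve_gmec(reduced)

    repacked = _apply_assignment(scaffold, reduced, assignment)
    prot_records = []
    for res in repacked.residues:
        prot_records.extend(residue_records(res, res.label, res.name))
    ts_recs = ts_records(ts_model, ts_pose)
    hbonds = detect_hydrogen_bonds(annotate_records(prot_records + ts_recs))
    be = binding_energy(prot_records, ts_recs, energy_params, excluded_pairs)
    return RepackResult(
        assignment={
            reduced.sites[i].res_id: reduced.sites[i].rotamers[r]
            for i, r in enumerate(assignment)
        },
        total_energy=float(total),
        hydrogen_bonds=hbonds,
        binding_energy=float(be),
        design_site_ids=[s.res_id for s in reduced.sites],
        repacked=repacked,
    )


def _apply_assignment(scaffold, table: EnergyTable, assignment: list[int]) -> ProteinStructure:
    residues = []
    chosen = {table.sites[i].res_id: (table.sites[i], assignment[i])
              for i in range(len(table.sites))}
    for res in scaffold.residues:
        clone = Residue(res.chain_id, res.number, res.name, res.icode)
        for n, a in res.atoms.items():
            clone.set_atom(n, a.coords.copy(), element=a.element)
        if res.res_id in chosen:
            site, r = chosen[res.res_id]
            for n in list(clone.atoms):
                if n not in _BACKBONE:
                    del clone.atoms[n]
            for rec in site.records[r].records:
                clone.set_atom(rec.name, rec.coords.copy(), element=rec.element)
        residues.append(clone)
    out = ProteinStructure(residues=residues, source_id=scaffold.source_id,
                           resolution=scaffold.resolution)
    out.hydrogens_built = scaffold.hydrogens_built
    return out


def hbond_recovery(
    predicted: Sequence[HBond] | Sequence[tuple],
    reference: Sequence[HBond] | Sequence[tuple],
) -> tuple[float, list, list]:
    """Fraction of reference hydrogen bonds present in the prediction.

    Bonds are identified by (donor heavy-atom id, acceptor id).  Returns
    (recovered_fraction, matched_keys, missed_keys); an empty reference is an
    error (the fraction would be undefined).
    """

    def _key(b):
        return b.key if isinstance(b, HBond) else (tuple(b[0]), tuple(b[1]))

    ref = {_key(b) for b in reference}
    if not ref:
        raise ValueError("empty reference hydrogen-bond set")
    pred = {_key(b) for b in predicted}
    matched = sorted(ref & pred)
    missed = sorted(ref - pred)
    return len(matched) / len(ref), matched, missed
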