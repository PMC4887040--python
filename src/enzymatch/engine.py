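"""Matching engine: enumerate site assignments, close loops, prune, rank.

For every surviving ordered pair of candidate sites the main loop (first
role -> TS -> second role) is closed from a deterministic multistart; closed
loops are deduplicated, constraint-checked and repulsion-pruned, then the
remaining motif roles are placed by side loops in a depth-first search over
unused sites.  Complete placements are assembled into full-atom matches,
re-checked against every motif constraint and every repulsion threshold, and
ranked by a weighted sum of normalized constraint deviation and repulsion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from . import templates
from .closure import close_loop_multistart, max_loop_length, sample_initial_loops
from .geometry import rmsd_no_fit, superpose
from .loops import SideLoopSpec, build_main_loop, main_loop_roles
from .motif import CatalyticMotif, ConstraintReport, attachment_block, check_match_constraints
from .pruning import PruningParams, dedup_loops, prune_by_repulsion, repulsion_energy
from .structure import ProteinStructure, Residue

__all__ = [
    "Match",
    "MatchConfig",
    "enumerate_assignments",
    "match_scaffold",
    "rank_matches",
    "ts_rmsd_vs_reference",
]

logger = logging.getLogger(__name__)

_BACKBONE = {"N", "CA", "C", "O", "H", "HA", "HA1", "HA2", "OXT"}


@dataclass
class MatchConfig:
    candidate_radius: float = 15.0
    closure_tolerance: float = 0.1
    grid_step: float = 120.0
    max_samples: int = 128
    seed: int = 0
    pruning: PruningParams = field(default_factory=PruningParams)
    max_matches: int = 1000
    rank_w_constraint: float = 1.0
    rank_w_repulsion: float = 1.0
    max_side_solutions: int = 4  # side-loop branching cap per role

    def __post_init__(self):
        if self.candidate_radius <= 0 or self.closure_tolerance <= 0:
            raise ValueError("radii and tolerances must be positive")


@dataclass
class Match:
    scaffold_id: str
    site_assignment: dict[str, tuple]
    ts_pose: dict[str, np.ndarray]
    residue_conformations: dict[str, dict[str, np.ndarray]]
    constraint_report: ConstraintReport
    repulsion: dict[str, float]
    rank_score: float = 0.0

    @property
    def repulsion_total(self) -> float:
        return float(sum(self.repulsion.values()))

    def assignment_labels(self) -> dict[str, str]:
        return {k: f"{v[0]}{v[1]}{v[2]}" for k, v in self.site_assignment.items()}


def _usable_for_role(motif: CatalyticMotif, role_id: str, site: Residue) -> bool:
    role = motif.role(role_id)
    if not site.has_backbone() or not site.usable_site:
        return False
    if site.is_proline:
        return False  # no repackable side chain / no amide H
    if role.interaction_via == "backbone":
        return True
    aa = role.allowed_aa[0] if "ANY" not in role.allowed_aa else site.name
    return aa in templates.STANDARD_AA


def enumerate_assignments(
    motif: CatalyticMotif,
    sites: Sequence[Residue],
    pruned_pairs: Optional[set[tuple]] = None,
) -> Iterator[dict[str, tuple]]:
    """Lazily yield injective role -> site-id maps in deterministic order.

    Roles follow motif order; sites are tried in (chain, number) order.  Pairs
    of site ids listed in ``pruned_pairs`` (reach pruning of the two main-loop
    roles) are skipped before yielding.
    """
    role_ids = motif.role_ids()
    r1, r2 = main_loop_roles(motif)
    usable = {
        role: [s for s in sites if _usable_for_role(motif, role, s)] for role in role_ids
    }
    pruned = pruned_pairs or set()

    def _rec(k: int, chosen: dict[str, tuple], used: set):
        if k == len(role_ids):
            yield dict(chosen)
            return
        role = role_ids[k]
        for s in usable[role]:
            if s.res_id in used:
                continue
            chosen[role] = s.res_id
            if role == r2 and r1 in chosen and (chosen[r1], s.res_id) in pruned:
                del chosen[role]
                continue
            used.add(s.res_id)
            yield from _rec(k + 1, chosen, used)
            used.discard(s.res_id)
            del chosen[role]

    yield from _rec(0, {}, set())


def ts_rmsd_vs_reference(match: Match, reference_ts_coords: dict[str, np.ndarray]) -> float:
    """No-fit heavy-atom RMSD of the matched TS against a reference pose,
    with correspondence by TS atom name, in the common scaffold frame."""
    names = sorted(n for n in match.ts_pose if not n.startswith("H"))
    missing = [n for n in names if n not in reference_ts_coords]
    if missing:
        raise KeyError(f"reference TS lacks atoms {missing}")
    a = np.array([match.ts_pose[n] for n in names])
    b = np.array([reference_ts_coords[n] for n in names])
    return rmsd_no_fit(a, b)


def ts_rmsd_fitted(match: Match, reference_ts_coords: dict[str, np.ndarray]) -> float:
    """Superposed (Kabsch) TS RMSD — reported alongside the no-fit value."""
    names = sorted(n for n in match.ts_pose if not n.startswith("H"))
    a = np.array([match.ts_pose[n] for n in names])
    b = np.array([reference_ts_coords[n] for n in names])
    return superpose(a, b)[0]


def rank_matches(
    matches: Sequence[Match],
    w_constraint: float = 1.0,
    w_repulsion: float = 1.0,
) -> list[Match]:
    """Stable deterministic ranking, ascending in
    ``w_c * rms_constraint_deviation + w_r * total_repulsion / 100 PEU``;
    ties break on lower repulsion, then lexicographic site assignment."""
    for m in matches:
        m.rank_score = (
            w_constraint * m.constraint_report.rms_deviation
            + w_repulsion * m.repulsion_total / 100.0
        )
    return sorted(
        matches,
        key=lambda m: (
            m.rank_score,
            m.repulsion_total,
            tuple(sorted(m.site_assignment.items())),
        ),
    )


# ---------------------------------------------------------------------------
# Assembly helpers


def _assemble_role(
    motif: CatalyticMotif,
    role_id: str,
    site: Residue,
    placed: dict[str, np.ndarray],
    ts_pose: Optional[dict[str, np.ndarray]] = None,
) -> dict[str, np.ndarray]:
    """Full-atom conformation of a role at a site from kinematically placed atoms.

    Backbone-interaction roles keep the site residue as-is.  Side-chain roles
    graft the role's amino acid onto the site backbone at the placed chi
    angles; for a covalent pseudo-bond to the TS the replaced heavy atom
    (e.g. serine OG, whose position is the TS nucleophile oxygen) and its
    dependent hydrogens are omitted.
    """
    from .fixtures import assemble_residue  # shared assembly logic

    role = motif.role(role_id)
    if role.interaction_via == "backbone":
        return {n: a.coords.copy() for n, a in site.atoms.items()}
    aa = role.allowed_aa[0] if "ANY" not in role.allowed_aa else site.name
    merged = {"N": site.coord("N"), "CA": site.coord("CA"), "C": site.coord("C")}
    merged.update({k: v for k, v in placed.items() if k not in ("N", "CA", "C")})
    drop: set[str] = set()
    block = attachment_block(motif, role_id)
    if block.partner == "TS" and block.distance[0] < 1.8 and ts_pose is not None:
        ext = templates.bonded_extension(aa, block.a_triple[0])
        if ext is not None:
            merged[ext] = np.asarray(ts_pose[block.b_triple[0]], float)
            drop = {ext}
    return assemble_residue(aa, merged, drop=drop)


def _heavy(atoms: dict[str, np.ndarray], radius_of) -> list[tuple[np.ndarray, float]]:
    return [
        (xyz, radius_of(name))
        for name, xyz in atoms.items()
        if not name.startswith("H") and not name.startswith(("1H", "2H", "3H"))
    ]


class _Repulsion:
    """Cached heavy-atom groups of the scaffold for repulsion staging."""

    def __init__(self, scaffold: ProteinStructure, candidate_ids: set):
        from .params import element_from_name, vdw_radius

        self._rad = lambda n: vdw_radius(element_from_name(n))
        self.backbone: dict[tuple, list] = {}
        template_atoms: list = []
        for res in scaffold.residues:
            heavy_bb = [
                (a.coords, a.vdw_radius)
                for n, a in res.atoms.items()
                if not a.is_hydrogen and n in _BACKBONE
            ]
            if res.res_id in candidate_ids:
                self.backbone[res.res_id] = heavy_bb
            else:
                template_atoms.extend(
                    (a.coords, a.vdw_radius) for a in res.heavy_atoms()
                )
        self.template = template_atoms

    def radius_of(self, name: str) -> float:
        return self._rad(name)

    def backbone_atoms(self, exclude: Iterable[tuple] = ()) -> list:
        ex = set(exclude)
        out = []
        for rid, atoms in self.backbone.items():
            if rid not in ex:
                out.extend(atoms)
        return out


def _loop_repulsion(groups: dict[str, dict], own_sites: dict[str, tuple], rep: _Repulsion) -> float:
    """Loop atoms vs candidate-site backbones, excluding each group's own anchor."""
    total = 0.0
    for gname, atoms in groups.items():
        own = own_sites.get(gname)
        bb = rep.backbone_atoms(exclude=(own,) if own else ())
        total += repulsion_energy(_heavy(atoms, rep.radius_of), bb)
    return total


def match_scaffold(
    scaffold: ProteinStructure,
    motif: CatalyticMotif,
    config: MatchConfig = MatchConfig(),
    sites: Optional[Sequence[Residue]] = None,
    reference_residues: Optional[Sequence] = None,
) -> list[Match]:
    """Full matching of a motif onto one scaffold; returns ranked matches.

    Candidate sites are either supplied directly or derived from reference
    residues (CSA-style catalytic annotation) via the candidate-radius rule.
    An empty list means the scaffold affords no feasible match.
    """
    if not scaffold.hydrogens_built:
        from .structure import build_hydrogens

        build_hydrogens(scaffold)
    if sites is None:
        if reference_residues is None:
            raise ValueError("provide candidate sites or reference residues")
        from .structure import candidate_sites

        sites = candidate_sites(scaffold, reference_residues, config.candidate_radius)
    sites = [s for s in sites if s.has_backbone() and s.usable_site]
    candidate_ids = {s.res_id for s in sites}
    rep = _Repulsion(scaffold, candidate_ids)
    r1, r2 = main_loop_roles(motif)
    side_specs = _side_specs(motif, r1, r2)
    prm = config.pruning

    sites1 = [s for s in sites if _usable_for_role(motif, r1, s)]
    sites2 = [s for s in sites if _usable_for_role(motif, r2, s)]

    # reach bound for the main loop is geometry-only: compute once
    reach_cache: dict[tuple, float] = {}

    def _main_reach(s1: Residue, s2: Residue) -> float:
        key = (s1.name, s2.name)
        if key not in reach_cache:
            loop = build_main_loop(motif, scaffold, r1, s1, r2, s2)
            reach_cache[key] = max_loop_length(
                loop, seed=config.seed, n_starts=12, n_random=256
            )
        return reach_cache[key]

    matches: list[Match] = []
    for s1 in sites1:
        for s2 in sites2:
            if s1.res_id == s2.res_id:
                continue
            dist = float(np.linalg.norm(s1.coord("CA") - s2.coord("CA")))
            if _main_reach(s1, s2) + prm.reach_margin < dist:
                continue
            loop = build_main_loop(motif, scaffold, r1, s1, r2, s2)
            starts = sample_initial_loops(
                loop, grid_step=config.grid_step,
                max_samples=config.max_samples, seed=config.seed,
            )
            closed = close_loop_multistart(loop, starts, config.closure_tolerance)
            closed.sort(key=lambda c: c.closure_deviation)
            closed = dedup_loops(closed, prm.dedup_rmsd)
            for sol in closed:
                groups = sol.group_coords(loop)
                # pruning (iii): constraints internal to the main loop
                internal = {"TS": groups["TS"], r1: groups[r1], r2: groups[r2]}
                if not _partial_constraints_ok(motif, internal):
                    continue
                # pruning (iv): main loop vs backbone
                e_main = _loop_repulsion(
                    {k: groups[k] for k in (r1, r2, "TS")},
                    {r1: s1.res_id, r2: s2.res_id},
                    rep,
                )
                if not prune_by_repulsion("main_loop", e_main, prm):
                    continue
                conf = {
                    r1: _assemble_role(motif, r1, s1, groups[r1], groups["TS"]),
                    r2: _assemble_role(motif, r2, s2, groups[r2], groups["TS"]),
                }
                assignment = {r1: s1.res_id, r2: s2.res_id}
                _extend_side_roles(
                    motif, scaffold, sites, side_specs, 0, assignment, conf,
                    groups["TS"], {"main_loop": e_main}, rep, config, matches,
                )
                if len(matches) >= config.max_matches:
                    logger.info("max matches cap (%d) hit", config.max_matches)
                    break
            if len(matches) >= config.max_matches:
                break
        if len(matches) >= config.max_matches:
            break
    matches = _dedup_matches(matches, prm.dedup_rmsd)
    return rank_matches(matches, config.rank_w_constraint, config.rank_w_repulsion)


def _side_specs(motif: CatalyticMotif, r1: str, r2: str) -> list[SideLoopSpec]:
    specs = []
    placed = {"TS", r1, r2}
    for role in motif.residues:
        if role.role_id in (r1, r2):
            continue
        block = attachment_block(motif, role.role_id)
        if block.partner not in placed:
            raise ValueError(
                f"side role {role.role_id} depends on unplaced {block.partner}"
            )
        specs.append(SideLoopSpec(motif, role.role_id, block))
        placed.add(role.role_id)
    return specs


def _partial_constraints_ok(motif: CatalyticMotif, coords: dict) -> bool:
    present = set(coords)
    for c in motif.constraints:
        if not c.roles() <= present:
            continue
        from .motif import constraint_deviation

        try:
            _, dev = constraint_deviation(c, lambda role, atom: coords[role][atom])
        except KeyError:
            continue
        if dev > 1e-6:
            return False
    return True


def _extend_side_roles(
    motif, scaffold, sites, side_specs, k, assignment, conf, ts_pose,
    repulsions, rep, config, matches,
):
    if len(matches) >= config.max_matches:
        return
    if k == len(side_specs):
        _finalize_match(motif, scaffold, assignment, conf, ts_pose, repulsions,
                        rep, config, matches)
        return
    spec = side_specs[k]
    partner_atoms = ts_pose if spec.partner == "TS" else conf[spec.partner]
    used = set(assignment.values())
    reach_cache = getattr(config, "_side_reach", None)
    if reach_cache is None:
        reach_cache = {}
        object.__setattr__(config, "_side_reach", reach_cache)
    b1 = spec.block.b_triple[0]
    for site in sites:
        if site.res_id in used or not _usable_for_role(motif, spec.role_id, site):
            continue
        # pruning (i) for side loops: anchor-to-site distance vs cached reach
        key = (spec.role_id, site.name if motif.role(spec.role_id).interaction_via == "side_chain" else "*")
        if key not in reach_cache:
            probe = spec.bind(partner_atoms, site)
            reach_cache[key] = max_loop_length(
                probe, seed=config.seed, n_starts=8, n_random=128
            )
        d = float(np.linalg.norm(np.asarray(partner_atoms[b1]) - site.coord("CA")))
        if d > reach_cache[key] + config.pruning.reach_margin:
            continue
        loop = spec.bind(partner_atoms, site)
        starts = sample_initial_loops(
            loop, grid_step=config.grid_step,
            max_samples=config.max_samples, seed=config.seed,
        )
        closed = close_loop_multistart(loop, starts, config.closure_tolerance)
        closed.sort(key=lambda c: c.closure_deviation)
        closed = dedup_loops(closed, config.pruning.dedup_rmsd)
        for sol in closed[: config.max_side_solutions]:
            groups = sol.group_coords(loop)
            placed = groups[spec.role_id]
            e_side = _loop_repulsion(
                {spec.role_id: placed}, {spec.role_id: site.res_id}, rep
            )
            if not prune_by_repulsion("side_loop", e_side, config.pruning):
                continue
            assignment[spec.role_id] = site.res_id
            conf[spec.role_id] = _assemble_role(motif, spec.role_id, site, placed, ts_pose)
            reps = dict(repulsions)
            reps[f"side:{spec.role_id}"] = e_side
            _extend_side_roles(
                motif, scaffold, sites, side_specs, k + 1, assignment, conf,
                ts_pose, reps, rep, config, matches,
            )
            del assignment[spec.role_id]
            conf.pop(spec.role_id, None)


def _finalize_match(
    motif, scaffold, assignment, conf, ts_pose, repulsions, rep, config, matches
):
    coords_map = {"TS": ts_pose, **conf}
    report = check_match_constraints(motif, coords_map)
    if not report.all_satisfied:
        return
    # whole match = all placed side chains + TS (heavy atoms)
    match_atoms: list = []
    for role_id, atoms in conf.items():
        own_bb_excluded = {
            n: x for n, x in atoms.items() if n not in _BACKBONE
        }
        match_atoms.extend(_heavy(own_bb_excluded, rep.radius_of))
    match_atoms.extend(_heavy(ts_pose, rep.radius_of))
    e_template = repulsion_energy(match_atoms, rep.template)
    if not prune_by_repulsion("match_vs_template", e_template, config.pruning):
        return
    e_backbone = 0.0
    for role_id, atoms in conf.items():
        sc = {n: x for n, x in atoms.items() if n not in _BACKBONE}
        e_backbone += repulsion_energy(
            _heavy(sc, rep.radius_of),
            rep.backbone_atoms(exclude=(assignment[role_id],)),
        )
    e_backbone += repulsion_energy(_heavy(ts_pose, rep.radius_of), rep.backbone_atoms())
    if not prune_by_repulsion("match_vs_backbone", e_backbone, config.pruning):
        return
    reps = dict(repulsions)
    reps["match_vs_template"] = e_template
    reps["match_vs_backbone"] = e_backbone
    matches.append(
        Match(
            scaffold_id=scaffold.source_id,
            site_assignment=dict(assignment),
            ts_pose={k: np.asarray(v).copy() for k, v in ts_pose.items()},
            residue_conformations={
                r: {n: np.asarray(x).copy() for n, x in atoms.items()}
                for r, atoms in conf.items()
            },
            constraint_report=report,
            repulsion=reps,
        )
    )


def _dedup_matches(matches: list[Match], threshold: float) -> list[Match]:
    """Merge matches with identical assignments and near-identical TS poses."""
    out: list[Match] = []
    for m in sorted(matches, key=lambda m: m.constraint_report.rms_deviation):
        dup = False
        for kept in out:
            if kept.site_assignment != m.site_assignment:
                continue
            names = sorted(m.ts_pose)
            r = rmsd_no_fit(
                np.array([m.ts_pose[n] for n in names]),
                np.array([kept.ts_pose[n] for n in names]),
            )
            if r <= threshold:
                dup = True
                break
        if not dup:
            out.append(m)
    return out
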