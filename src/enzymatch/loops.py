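"""Compile a motif + site assignment into kinematic loops.

The *main loop* threads: start-anchor backbone (N, CA, C of the first site)
-> first role's side chain -> constraint pseudo-bond into the TS -> the TS
internal frame (plus its rotatable torsions) -> constraint pseudo-bond out of
the TS -> second role's side chain rebuilt in reverse -> computed backbone of
the second site, whose deviation from the real end anchor is the closure
objective.  Every remaining role contributes one *side loop*: its functional
group is placed off already-positioned atoms (TS or an earlier role) through
its constraint pseudo-bond and rebuilt in reverse down to a computed backbone
compared against its own site's anchor.

Constraint distances act as pseudo-bond lengths frozen at their optimal
values; constraint angles enter as fixed NeRF bond angles at the optimum and
constraint dihedrals become bounded torsion variables (optimum +/- tolerance).
Dihedrals absent from the motif are free torsions.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np

from . import templates
from .geometry import angle as _angle
from .geometry import ic_from_points
from .kinematics import ChainStep, KinematicChain, TorsionVar
from .motif import AttachmentBlock, CatalyticMotif, attachment_block
from .structure import ProteinStructure, Residue, TSModel

__all__ = [
    "KinematicLoop",
    "SideLoopSpec",
    "build_loops",
    "build_main_loop",
    "main_loop_roles",
    "FREE_TOLERANCE_DEG",
]

# A dihedral tolerance at or above this value is treated as a free torsion.
FREE_TOLERANCE_DEG = 180.0

# Chi angles adjacent to planar groups sample a 180-degree grid.
_CHI_SP2 = {
    ("HIS", 2), ("ASP", 2), ("ASN", 2), ("PHE", 2), ("TYR", 2), ("TRP", 2),
    ("GLU", 3), ("GLN", 3), ("ARG", 4),
}


@dataclass
class KinematicLoop:
    chain: KinematicChain
    kind: str  # "main" | "side"
    roles: tuple[str, ...]
    start_anchor: tuple  # res_id of the anchoring site
    end_anchor: tuple  # res_id whose backbone is the closure target
    target_coords: np.ndarray  # (3, 3): N, CA, C of the end anchor
    target_indices: list[int]  # computed N, CA, C atom indices in the chain
    terminal_ca_index: int
    start_ca_coord: np.ndarray
    includes_ts: bool

    @property
    def free_torsions(self) -> list[int]:
        return [i for i, v in enumerate(self.chain.variables) if not v.bounded]

    @property
    def bounded_torsions(self) -> list[int]:
        return [i for i, v in enumerate(self.chain.variables) if v.bounded]


@lru_cache(maxsize=64)
def _ref_atoms(resname: str):
    chis = [47.0] * templates.N_CHI[resname]
    return templates.build_residue(
        resname, *templates._REF_SEED, chis=chis, include_hydrogens=True
    )


def _grid_kind(resname: str, chi: int) -> str:
    return "sp2" if (resname, chi) in _CHI_SP2 else "sp3"


class _ChainBuilder:
    def __init__(self, fixed: list[tuple[str, np.ndarray]]):
        self.fixed_names = [n for n, _ in fixed]
        self.fixed_coords = np.array([c for _, c in fixed], dtype=float)
        self.steps: list[ChainStep] = []
        self.names: list[str] = []
        self.variables: list[TorsionVar] = []
        self.groups: dict[str, list[int]] = {}
        self._index: dict[str, int] = {n: i for i, n in enumerate(self.fixed_names)}

    def idx(self, name: str) -> int:
        return self._index[name]

    def new_var(self, var: TorsionVar) -> int:
        self.variables.append(var)
        return len(self.variables) - 1

    def add_step(
        self,
        name: str,
        frame: tuple[str, str, str],
        length: float,
        angle: float,
        torsion_offset: float = 0.0,
        var_index: int = -1,
        var_sign: float = 1.0,
        group: Optional[str] = None,
    ) -> int:
        fidx = tuple(self.idx(f) for f in frame)
        self.steps.append(
            ChainStep(name, fidx, float(length), float(angle), float(torsion_offset),
                      var_index, var_sign)
        )
        self.names.append(name)
        i = len(self.fixed_names) + len(self.steps) - 1
        self._index[name] = i
        if group:
            self.groups.setdefault(group, []).append(i)
        return i

    def build(self) -> KinematicChain:
        return KinematicChain(
            fixed_coords=self.fixed_coords,
            steps=self.steps,
            variables=self.variables,
            atom_names=self.names,
            groups=self.groups,
        )


def _constraint_torsion_var(
    cb: _ChainBuilder, name: str, spec: Optional[tuple[float, float]], grid_kind: str = "sp3"
) -> tuple[float, int]:
    """Return (offset, var_index) for an attachment torsion slot."""
    if spec is None or spec[1] >= FREE_TOLERANCE_DEG:
        seed = spec[0] if spec else (180.0 if grid_kind == "sp3" else 0.0)
        v = cb.new_var(TorsionVar(name, seed=seed, grid_kind=grid_kind))
        return 0.0, v
    opt, tol = spec
    v = cb.new_var(TorsionVar(name, lower=opt - tol, upper=opt + tol, seed=opt))
    return 0.0, v


def _add_forward_sidechain(
    cb: _ChainBuilder, role: str, resname: str, a1: str
) -> None:
    """Place the heavy-atom path backbone->A1 of a role's side chain."""
    chi_vars: dict[int, int] = {}
    for row in templates.sidechain_path(resname, a1):
        spec = row.torsion
        if spec.kind == "chi":
            k = spec.chi
            if k not in chi_vars:
                chi_vars[k] = cb.new_var(
                    TorsionVar(f"{role}.chi{k}", grid_kind=_grid_kind(resname, k))
                )
            cb.add_step(
                f"{role}.{row.name}",
                tuple(f"{role}.{f}" for f in row.frame),
                row.length, row.angle,
                torsion_offset=spec.value, var_index=chi_vars[k], var_sign=spec.sign,
                group=role,
            )
        else:
            cb.add_step(
                f"{role}.{row.name}",
                tuple(f"{role}.{f}" for f in row.frame),
                row.length, row.angle, torsion_offset=spec.value, group=role,
            )


def _add_ts(
    cb: _ChainBuilder, ts: TSModel, b_triple: tuple[str, str, str]
) -> None:
    """Place the remaining TS atoms once B1, B2, B3 are positioned.

    With no rotatable torsions the TS attaches as a rigid body to the
    (B1,B2,B3) frame; rotatable bonds introduce one free variable each, with
    downstream atoms placed along a bond-graph spanning tree.
    """
    ref = ts.reference_coords()
    placed = list(b_triple)
    remaining = [n for n in ts.atom_names() if n not in placed]
    rot = {frozenset(p) for p in ts.rotatable}
    if not rot:
        for n in remaining:
            ic = ic_from_points(ref[b_triple[0]], ref[b_triple[1]], ref[b_triple[2]], ref[n])
            cb.add_step(
                f"TS.{n}", tuple(f"TS.{b}" for b in b_triple),
                ic.bond_length, ic.bond_angle, torsion_offset=ic.torsion, group="TS",
            )
        return
    # spanning tree from the attachment triple over the bond graph
    nbrs: dict[str, list[str]] = {n: [] for n in ts.atom_names()}
    for x, y in ts.bonds():
        nbrs[x].append(y)
        nbrs[y].append(x)
    parent: dict[str, str] = {}
    order: list[str] = []
    queue = list(placed)
    seen = set(placed)
    while queue:
        cur = queue.pop(0)
        for nb in nbrs[cur]:
            if nb not in seen:
                seen.add(nb)
                parent[nb] = cur
                order.append(nb)
                queue.append(nb)
    bond_var: dict[frozenset, int] = {}
    placed_set = set(placed)
    for n in order:
        p = parent[n]
        gp = parent.get(p) or next(
            (x for x in (b_triple[1], b_triple[0], b_triple[2]) if x != p), b_triple[0]
        )
        ggp = parent.get(gp) or next(
            (x for x in (b_triple[0], b_triple[2], b_triple[1]) if x not in (p, gp)),
            b_triple[0],
        )
        ic = ic_from_points(ref[ggp], ref[gp], ref[p], ref[n])
        axis = frozenset((gp, p))
        if axis in rot:
            if axis not in bond_var:
                bond_var[axis] = cb.new_var(
                    TorsionVar(f"TS.{gp}-{p}", seed=ic.torsion, grid_kind="sp3")
                )
                cb.add_step(
                    f"TS.{n}", (f"TS.{ggp}", f"TS.{gp}", f"TS.{p}"),
                    ic.bond_length, ic.bond_angle, torsion_offset=0.0,
                    var_index=bond_var[axis], group="TS",
                )
                continue
            # sibling across the same rotatable bond: fixed offset from the var
            first_seed = next(
                v.seed for i, v in enumerate(cb.variables) if i == bond_var[axis]
            )
            cb.add_step(
                f"TS.{n}", (f"TS.{ggp}", f"TS.{gp}", f"TS.{p}"),
                ic.bond_length, ic.bond_angle,
                torsion_offset=float(ic.torsion - first_seed),
                var_index=bond_var[axis], group="TS",
            )
            continue
        cb.add_step(
            f"TS.{n}", (f"TS.{ggp}", f"TS.{gp}", f"TS.{p}"),
            ic.bond_length, ic.bond_angle, torsion_offset=ic.torsion, group="TS",
        )
        placed_set.add(n)


def _add_reverse_residue(
    cb: _ChainBuilder,
    role: str,
    resname: str,
    block: AttachmentBlock,
    partner_prefix: str,
    via_backbone: bool,
) -> None:
    """Place a role's residue outward from the partner triple through the
    constraint pseudo-bond, finishing at the computed backbone N, CA, C."""
    a1, a2, a3 = block.a_triple
    b1, b2, b3 = (f"{partner_prefix}.{x}" for x in block.b_triple)
    ref = _ref_atoms(resname)
    # A1 from (B3, B2, B1)
    off, v = _constraint_torsion_var(cb, f"{role}.tB", block.torsion_b)
    cb.add_step(
        f"{role}.{a1}", (b3, b2, b1), block.distance[0], block.angle_b[0],
        torsion_offset=off, var_index=v, group=role,
    )
    # A2 from (B2, B1, A1): internal residue bond, constraint angle_a
    off, v = _constraint_torsion_var(cb, f"{role}.tAB", block.torsion_ab)
    cb.add_step(
        f"{role}.{a2}", (b2, b1, f"{role}.{a1}"),
        float(np.linalg.norm(ref[a1] - ref[a2])), block.angle_a[0],
        torsion_offset=off, var_index=v, group=role,
    )
    # A3 from (B1, A1, A2): fully internal geometry, constraint torsion_a
    off, v = _constraint_torsion_var(cb, f"{role}.tA", block.torsion_a)
    cb.add_step(
        f"{role}.{a3}", (b1, f"{role}.{a1}", f"{role}.{a2}"),
        float(np.linalg.norm(ref[a2] - ref[a3])),
        _angle(ref[a1], ref[a2], ref[a3]),
        torsion_offset=off, var_index=v, group=role,
    )
    if via_backbone:
        # triple is (H, N, CA); one fixed step places C
        ic = ic_from_points(ref["H"], ref["N"], ref["CA"], ref["C"])
        cb.add_step(
            f"{role}.C", (f"{role}.H", f"{role}.N", f"{role}.CA"),
            ic.bond_length, ic.bond_angle, torsion_offset=ic.torsion, group=role,
        )
        return
    chi_vars: dict[int, int] = {}
    for row in templates.reversed_rows(resname, (a1, a2, a3)):
        spec = row.torsion
        if spec.kind == "chi":
            k = spec.chi
            if k not in chi_vars:
                chi_vars[k] = cb.new_var(
                    TorsionVar(f"{role}.chi{k}", grid_kind=_grid_kind(resname, k))
                )
            cb.add_step(
                f"{role}.{row.name}", tuple(f"{role}.{f}" for f in row.frame),
                row.length, row.angle,
                torsion_offset=spec.value, var_index=chi_vars[k], var_sign=spec.sign,
                group=role,
            )
        else:
            cb.add_step(
                f"{role}.{row.name}", tuple(f"{role}.{f}" for f in row.frame),
                row.length, row.angle, torsion_offset=spec.value, group=role,
            )


def main_loop_roles(motif: CatalyticMotif) -> tuple[str, str]:
    """The two roles threaded by the main loop: the first two side-chain roles
    whose attachment partner is the TS, in motif file order."""
    cands = []
    for r in motif.residues:
        if r.interaction_via != "side_chain":
            continue
        try:
            block = attachment_block(motif, r.role_id)
        except ValueError:
            continue
        if block.partner == "TS":
            cands.append(r.role_id)
    if len(cands) < 2:
        raise ValueError(
            "main loop needs two side-chain roles constrained to the TS; "
            f"found {cands}"
        )
    return cands[0], cands[1]


def _site_aa(motif: CatalyticMotif, role_id: str, site: Residue) -> str:
    """Amino-acid identity a role assumes at a site (grafted during design)."""
    role = motif.role(role_id)
    if role.interaction_via == "backbone":
        return site.name
    if "ANY" in role.allowed_aa:
        return site.name
    return role.allowed_aa[0]


def build_main_loop(
    motif: CatalyticMotif,
    scaffold: ProteinStructure,
    role1: str,
    site1: Residue,
    role2: str,
    site2: Residue,
) -> KinematicLoop:
    for role_id, site in ((role1, site1), (role2, site2)):
        if motif.role(role_id).interaction_via == "backbone":
            raise ValueError(f"backbone-interaction role {role_id} cannot anchor a main loop")
        if not site.has_backbone():
            raise ValueError(f"site {site.label} lacks a complete backbone frame")
    aa1 = _site_aa(motif, role1, site1)
    aa2 = _site_aa(motif, role2, site2)
    block1 = attachment_block(motif, role1)
    block2 = attachment_block(motif, role2)
    if block1.partner != "TS" or block2.partner != "TS":
        raise ValueError("main-loop roles must attach to the TS")

    cb = _ChainBuilder(
        [
            (f"{role1}.C", site1.coord("C")),
            (f"{role1}.N", site1.coord("N")),
            (f"{role1}.CA", site1.coord("CA")),
        ]
    )
    # forward side chain of role 1 up to its functional atom A1
    _add_forward_sidechain(cb, role1, aa1, block1.a_triple[0])
    # into the TS: B1 from (A3, A2, A1)
    a1, a2, a3 = (f"{role1}.{x}" for x in block1.a_triple)
    b1, b2, b3 = block1.b_triple
    ts_ref = motif.ts.reference_coords()
    off, v = _constraint_torsion_var(cb, f"{role1}.tA", block1.torsion_a)
    cb.add_step(f"TS.{b1}", (a3, a2, a1), block1.distance[0], block1.angle_a[0],
                torsion_offset=off, var_index=v, group="TS")
    off, v = _constraint_torsion_var(cb, f"{role1}.tAB", block1.torsion_ab)
    cb.add_step(f"TS.{b2}", (a2, a1, f"TS.{b1}"),
                float(np.linalg.norm(ts_ref[b1] - ts_ref[b2])), block1.angle_b[0],
                torsion_offset=off, var_index=v, group="TS")
    off, v = _constraint_torsion_var(cb, f"{role1}.tB", block1.torsion_b)
    cb.add_step(f"TS.{b3}", (a1, f"TS.{b1}", f"TS.{b2}"),
                float(np.linalg.norm(ts_ref[b2] - ts_ref[b3])),
                _angle(ts_ref[b1], ts_ref[b2], ts_ref[b3]),
                torsion_offset=off, var_index=v, group="TS")
    _add_ts(cb, motif.ts, (b1, b2, b3))
    # out of the TS into role 2, rebuilt in reverse to its backbone
    _add_reverse_residue(cb, role2, aa2, block2, "TS", via_backbone=False)

    chain = cb.build()
    loop = KinematicLoop(
        chain=chain,
        kind="main",
        roles=(role1, role2),
        start_anchor=site1.res_id,
        end_anchor=site2.res_id,
        target_coords=np.array([site2.coord("N"), site2.coord("CA"), site2.coord("C")]),
        target_indices=[chain.index_of(f"{role2}.{n}") for n in ("N", "CA", "C")],
        terminal_ca_index=chain.index_of(f"{role2}.CA"),
        start_ca_coord=site1.coord("CA"),
        includes_ts=True,
    )
    return loop


@dataclass
class SideLoopSpec:
    """A side loop before its partner coordinates are known.

    ``bind`` fixes the partner triple (TS atoms or atoms of an earlier role,
    taken from a partially assembled match) and the candidate site, yielding a
    closable :class:`KinematicLoop`.
    """

    motif: CatalyticMotif
    role_id: str
    block: AttachmentBlock

    @property
    def partner(self) -> str:
        return self.block.partner

    def bind(self, partner_coords: dict[str, np.ndarray], site: Residue) -> KinematicLoop:
        role = self.motif.role(self.role_id)
        via_backbone = role.interaction_via == "backbone"
        if not site.has_backbone():
            raise ValueError(f"site {site.label} lacks a backbone frame")
        aa = _site_aa(self.motif, self.role_id, site)
        b1, b2, b3 = self.block.b_triple
        pref = self.partner
        cb = _ChainBuilder(
            [
                (f"{pref}.{b3}", partner_coords[b3]),
                (f"{pref}.{b2}", partner_coords[b2]),
                (f"{pref}.{b1}", partner_coords[b1]),
            ]
        )
        _add_reverse_residue(cb, self.role_id, aa, self.block, pref, via_backbone)
        chain = cb.build()
        return KinematicLoop(
            chain=chain,
            kind="side",
            roles=(self.role_id,),
            start_anchor=site.res_id,
            end_anchor=site.res_id,
            target_coords=np.array([site.coord("N"), site.coord("CA"), site.coord("C")]),
            target_indices=[chain.index_of(f"{self.role_id}.{n}") for n in ("N", "CA", "C")],
            terminal_ca_index=chain.index_of(f"{self.role_id}.CA"),
            start_ca_coord=np.asarray(partner_coords[b1], float),
            includes_ts=False,
        )


def build_loops(
    motif: CatalyticMotif,
    site_assignment: dict[str, tuple],
    scaffold: ProteinStructure,
) -> tuple[KinematicLoop, list[SideLoopSpec]]:
    """Build the main loop and the side-loop specs for a full assignment.

    The assignment maps every role id to a distinct residue id in the
    scaffold.  Side loops are returned in motif order; each one's partner must
    be the TS or a role placed before it.
    """
    ids = list(site_assignment.values())
    if len(set(ids)) != len(ids):
        raise ValueError("site assignment must map roles to distinct residues")
    r1, r2 = main_loop_roles(motif)
    main = build_main_loop(
        motif, scaffold, r1, scaffold.get(site_assignment[r1]),
        r2, scaffold.get(site_assignment[r2]),
    )
    placed = {"TS", r1, r2}
    sides = []
    for role in motif.residues:
        if role.role_id in (r1, r2):
            continue
        block = attachment_block(motif, role.role_id)
        if block.partner not in placed:
            raise ValueError(
                f"side loop {role.role_id} depends on {block.partner}, "
                "which is not placed yet (reorder the motif residues)"
            )
        sides.append(SideLoopSpec(motif, role.role_id, block))
        placed.add(role.role_id)
    return main, sides
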