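"""Catalytic motifs: residue roles and geometric constraints.

A motif couples a transition-state (TS) model to a set of residue *roles*
(e.g. SER1, HIS2, ASP3 of a catalytic triad plus oxyanion-hole backbone
donors) through distance / angle / improper-dihedral constraints, each with
an optimal value and a tolerance.  A *minimal* motif keeps only the catalytic
roles; a *complex* motif adds the residues that stabilize the catalytic
residues and the residues that bind the TS.

Constraints reference atoms as ``(role_id, atom_name)`` pairs, with the
special role id ``TS`` naming transition-state atoms.  For matching, the
constraints attached to a role are compiled into a six-degree-of-freedom
attachment block (one distance, two angles, up to three dihedrals) between a
residue atom triple and a partner atom triple (TS atoms or atoms of another,
earlier-placed role); dihedrals omitted from the file are free torsions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import yaml

from .geometry import measure, wrap_degrees
from .structure import TSModel

__all__ = [
    "GeometricConstraint",
    "MotifResidue",
    "CatalyticMotif",
    "AttachmentBlock",
    "ConstraintReport",
    "parse_motif",
    "serialize_motif",
    "constraint_deviation",
    "check_match_constraints",
]

ROLE_CLASSES = ("catalytic", "stabilizes_catalytic", "stabilizes_TS")

# Normalization used to mix units when ranking: 1 A of distance deviation is
# weighted like 10 degrees of angular deviation.  Configurable at call sites.
ANGLE_NORM_DEG = 10.0

CONSTRAINT_KINDS = ("distance", "angle", "improper_dihedral", "dihedral")


@dataclass(frozen=True)
class GeometricConstraint:
    kind: str
    atom_refs: tuple[tuple[str, str], ...]  # ((role_id | "TS", atom_name), ...)
    optimal: float
    tolerance: float
    periodic: bool = True  # dihedrals wrap on the circle

    def __post_init__(self):
        if self.kind not in CONSTRAINT_KINDS:
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        n_expected = {"distance": 2, "angle": 3}.get(self.kind, 4)
        if len(self.atom_refs) != n_expected:
            raise ValueError(
                f"{self.kind} constraint needs {n_expected} atom refs, got {len(self.atom_refs)}"
            )
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")

    @property
    def is_angular(self) -> bool:
        return self.kind != "distance"

    def roles(self) -> set[str]:
        return {ref[0] for ref in self.atom_refs}


@dataclass(frozen=True)
class MotifResidue:
    role_id: str
    allowed_aa: tuple[str, ...]  # ("ANY",) for backbone roles
    role_class: str
    interaction_via: str  # "side_chain" | "backbone"
    triple: tuple[str, str, str]  # (A1, A2, A3): functional atom and inward path

    def __post_init__(self):
        if self.role_class not in ROLE_CLASSES:
            raise ValueError(f"unknown role class {self.role_class!r}")
        if self.interaction_via not in ("side_chain", "backbone"):
            raise ValueError(f"unknown interaction {self.interaction_via!r}")


@dataclass
class CatalyticMotif:
    name: str
    residues: list[MotifResidue]
    ts: TSModel
    constraints: list[GeometricConstraint]

    def __post_init__(self):
        roles = {r.role_id for r in self.residues}
        ts_atoms = set(self.ts.atom_names())
        for c in self.constraints:
            for role, atom in c.atom_refs:
                if role == "TS":
                    if atom not in ts_atoms:
                        raise ValueError(f"constraint references unknown TS atom {atom!r}")
                elif role not in roles:
                    raise ValueError(f"constraint references undeclared role {role!r}")

    def role(self, role_id: str) -> MotifResidue:
        for r in self.residues:
            if r.role_id == role_id:
                return r
        raise KeyError(role_id)

    def role_ids(self) -> list[str]:
        return [r.role_id for r in self.residues]

    def catalytic_roles(self) -> list[MotifResidue]:
        return [r for r in self.residues if r.role_class == "catalytic"]

    def minimal_view(self) -> "CatalyticMotif":
        """Restrict to catalytic roles; constraints among kept roles + TS only."""
        kept = {r.role_id for r in self.catalytic_roles()} | {"TS"}
        return CatalyticMotif(
            name=f"{self.name}_minimal",
            residues=list(self.catalytic_roles()),
            ts=self.ts,
            constraints=[c for c in self.constraints if c.roles() <= kept],
        )

    def constraints_for_role(self, role_id: str) -> list[GeometricConstraint]:
        return [c for c in self.constraints if role_id in c.roles()]


@dataclass
class AttachmentBlock:
    """Six-DOF attachment of a role's functional triple to a partner triple.

    ``a_triple`` are residue atoms (A1 nearest the partner), ``b_triple``
    partner atoms (B1 nearest the residue) on the TS or another role.
    Dihedral entries of None are free torsions.
    """

    role_id: str
    partner: str  # "TS" or another role_id
    a_triple: tuple[str, str, str]
    b_triple: tuple[str, str, str]
    distance: tuple[float, float]  # (optimal, tolerance)
    angle_a: tuple[float, float]  # A2-A1-B1
    angle_b: tuple[float, float]  # A1-B1-B2
    torsion_a: Optional[tuple[float, float]] = None  # A3-A2-A1-B1
    torsion_ab: Optional[tuple[float, float]] = None  # A2-A1-B1-B2
    torsion_b: Optional[tuple[float, float]] = None  # A1-B1-B2-B3


@dataclass
class ConstraintResult:
    constraint: GeometricConstraint
    measured: float
    deviation: float  # beyond tolerance; 0 = satisfied


@dataclass
class ConstraintReport:
    results: list[ConstraintResult]
    all_satisfied: bool
    rms_deviation: float


def constraint_deviation(
    constraint: GeometricConstraint,
    resolve: Callable[[str, str], np.ndarray],
) -> tuple[float, float]:
    """Measured value and deviation beyond tolerance for one constraint.

    ``resolve(role, atom)`` returns coordinates.  Dihedral differences use
    shortest-arc wrapping; deviation is ``max(0, |delta| - tolerance)``.
    """
    pts = [resolve(role, atom) for role, atom in constraint.atom_refs]
    kind = "dihedral" if constraint.kind == "improper_dihedral" else constraint.kind
    measured = measure(kind, pts)
    delta = measured - constraint.optimal
    if constraint.is_angular and constraint.kind != "angle" and constraint.periodic:
        delta = wrap_degrees(delta)
    deviation = max(0.0, abs(delta) - constraint.tolerance)
    return measured, deviation


def check_match_constraints(
    motif: CatalyticMotif,
    match_coords: dict[str, dict[str, np.ndarray]],
    angle_norm_deg: float = ANGLE_NORM_DEG,
) -> ConstraintReport:
    """Evaluate every motif constraint against resolved match coordinates.

    ``match_coords`` maps role ids (and "TS") to atom-name -> coordinate
    dictionaries.  The RMS deviation mixes units by normalizing distances by
    1 A and angles by ``angle_norm_deg`` degrees.
    """

    def resolve(role: str, atom: str) -> np.ndarray:
        try:
            return match_coords[role][atom]
        except KeyError:
            raise KeyError(f"unresolved atom {role}.{atom} in match coordinates") from None

    results = []
    norm_sq = []
    for c in motif.constraints:
        measured, deviation = constraint_deviation(c, resolve)
        results.append(ConstraintResult(c, measured, deviation))
        norm = angle_norm_deg if c.is_angular else 1.0
        norm_sq.append((deviation / norm) ** 2)
    rms = float(np.sqrt(np.mean(norm_sq))) if norm_sq else 0.0
    return ConstraintReport(
        results=results,
        all_satisfied=all(r.deviation == 0.0 for r in results),
        rms_deviation=rms,
    )


# ---------------------------------------------------------------------------
# Attachment-block compilation (used by loop building)


def attachment_block(motif: CatalyticMotif, role_id: str) -> AttachmentBlock:
    """Compile a role's constraints into its six-DOF attachment block.

    The block is identified from the single distance constraint between the
    role and its partner (TS or another role); angle and dihedral constraints
    matching the canonical atom patterns fill the remaining slots.
    """
    role = motif.role(role_id)
    a1, a2, a3 = role.triple
    dists = [
        c
        for c in motif.constraints_for_role(role_id)
        if c.kind == "distance" and (role_id, a1) in c.atom_refs
    ]
    if len(dists) != 1:
        raise ValueError(
            f"role {role_id} needs exactly one distance constraint on its functional "
            f"atom {a1!r}; found {len(dists)}"
        )
    dist = dists[0]
    (b_role, b1) = next(ref for ref in dist.atom_refs if ref != (role_id, a1))

    block = AttachmentBlock(
        role_id=role_id,
        partner=b_role,
        a_triple=(a1, a2, a3),
        b_triple=(b1, "", ""),
        distance=(dist.optimal, dist.tolerance),
        angle_a=(0.0, 0.0),
        angle_b=(0.0, 0.0),
    )

    A = lambda atom: (role_id, atom)  # noqa: E731
    B = lambda atom: (b_role, atom)  # noqa: E731

    b2 = b3 = None
    angle_a = angle_b = None
    for c in motif.constraints_for_role(role_id):
        refs = c.atom_refs
        if c.kind == "angle":
            if refs[:2] == (A(a2), A(a1)) and refs[2][0] == b_role and refs[2][1] == b1:
                angle_a = (c.optimal, c.tolerance)
            elif refs[0] == A(a1) and refs[1] == B(b1) and refs[2][0] == b_role:
                angle_b = (c.optimal, c.tolerance)
                b2 = refs[2][1]
        elif c.kind in ("dihedral", "improper_dihedral"):
            if refs == (A(a3), A(a2), A(a1), B(b1)):
                block.torsion_a = (c.optimal, c.tolerance)
            elif refs[:3] == (A(a2), A(a1), B(b1)) and refs[3][0] == b_role:
                block.torsion_ab = (c.optimal, c.tolerance)
                if b2 is None:
                    b2 = refs[3][1]
            elif refs[0] == A(a1) and refs[1] == B(b1) and refs[2][0] == b_role and refs[3][0] == b_role:
                block.torsion_b = (c.optimal, c.tolerance)
                b2 = b2 or refs[2][1]
                b3 = refs[3][1]
    if angle_a is None or angle_b is None:
        raise ValueError(
            f"role {role_id} attachment needs angle constraints A2-A1-B1 and A1-B1-B2"
        )
    block.angle_a = angle_a
    block.angle_b = angle_b
    if b3 is None:
        b3 = _third_partner_atom(motif, b_role, b1, b2)
    block.b_triple = (b1, b2, b3)
    return block


def _third_partner_atom(motif: CatalyticMotif, b_role: str, b1: str, b2: str) -> str:
    """Pick a third partner atom bonded to B2 (for dihedral frames)."""
    if b_role == "TS":
        for x, y in motif.ts.bonds():
            for cand, other in ((x, y), (y, x)):
                if other == b2 and cand not in (b1, b2):
                    return cand
        # fall back to any third atom
        for n in motif.ts.atom_names():
            if n not in (b1, b2):
                return n
        raise ValueError("TS model too small for a dihedral frame")
    triple = motif.role(b_role).triple
    for n in triple:
        if n not in (b1, b2):
            return n
    raise ValueError(f"cannot find third frame atom on role {b_role}")


# ---------------------------------------------------------------------------
# Serialization


def serialize_motif(motif: CatalyticMotif) -> str:
    doc = {
        "name": motif.name,
        "ts": yaml.safe_load(motif.ts.to_yaml()),
        "residues": [
            {
                "role": r.role_id,
                "aa": list(r.allowed_aa),
                "class": r.role_class,
                "via": r.interaction_via,
                "triple": list(r.triple),
            }
            for r in motif.residues
        ],
        "constraints": [
            {
                "kind": c.kind,
                "atoms": [[role, atom] for role, atom in c.atom_refs],
                "optimal": c.optimal,
                "tolerance": c.tolerance,
                **({} if c.periodic else {"periodic": False}),
            }
            for c in motif.constraints
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def parse_motif(text: str) -> CatalyticMotif:
    """Parse a motif file (YAML).  ``serialize_motif`` round-trips exactly."""
    doc = yaml.safe_load(text)
    ts = TSModel.from_yaml(yaml.safe_dump(doc["ts"]))
    residues = []
    for r in doc["residues"]:
        aa = r.get("aa", "ANY")
        if isinstance(aa, str):
            aa = [aa]
        residues.append(
            MotifResidue(
                role_id=r["role"],
                allowed_aa=tuple(a.upper() for a in aa),
                role_class=r["class"],
                interaction_via=r.get("via", "side_chain"),
                triple=tuple(r["triple"]),
            )
        )
    constraints = []
    for c in doc.get("constraints", []):
        constraints.append(
            GeometricConstraint(
                kind=c["kind"],
                atom_refs=tuple((ref[0], ref[1]) for ref in c["atoms"]),
                optimal=float(c["optimal"]),
                tolerance=float(c["tolerance"]),
                periodic=bool(c.get("periodic", True)),
            )
        )
    return CatalyticMotif(
        name=doc.get("name", "motif"), residues=residues, ts=ts, constraints=constraints
    )
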