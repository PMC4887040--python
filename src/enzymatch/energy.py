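"""Molecular-mechanics-style scoring surrogate (PEU = package energy units).

Three terms act between atom groups:

* van der Waals — repulsion linearized below the clash onset ``c*(Ri+Rj)``
  (robust against deep overlaps), with a capped ``r^-6`` attractive tail;
* a directional 10-12 hydrogen-bond term between polar hydrogens and
  acceptors (O; N without attached hydrogens), gated on the D-H...A angle;
* screened Coulomb electrostatics with a distance-dependent dielectric
  (eps = 4r), capped per pair.

All terms are finite for any geometry.  Absolute magnitudes define this
model's own unit scale; comparisons across different energy functions are
not meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "EnergyParams",
    "AtomRecord",
    "AtomRecords",
    "interaction_energy",
    "HBond",
    "detect_hydrogen_bonds",
]


@dataclass(frozen=True)
class EnergyParams:
    k_rep: float = 10.0  # PEU at full overlap per clashing pair
    clash_onset: float = 0.85  # fraction of Ri+Rj where repulsion begins
    eps_att: float = 0.05  # depth scale of the attractive tail
    vdw_cutoff: float = 6.0
    eps_hb: float = 2.5  # ideal hydrogen-bond reward (PEU)
    r0_hb: float = 1.9  # ideal H...acceptor distance (A)
    hb_cutoff: float = 2.6
    coulomb_k: float = 332.0
    dielectric_slope: float = 4.0  # eps(r) = slope * r
    elec_cutoff: float = 8.0
    elec_cap: float = 5.0


DEFAULT_ENERGY_PARAMS = EnergyParams()

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "H", "HA", "HA1", "HA2", "OXT"}


@dataclass
class AtomRecord:
    """One atom prepared for scoring: identity, parameters and H-bond typing."""

    unit: str  # residue label or "TS"
    name: str
    element: str
    coords: np.ndarray
    radius: float
    charge: float
    polar_h_parent: Optional[str] = None  # heavy-atom name if this is a polar H
    parent_coords: Optional[np.ndarray] = None
    is_acceptor: bool = False

    @property
    def atom_id(self) -> tuple[str, str]:
        return (self.unit, self.name)


def annotate_records(records: list[AtomRecord]) -> list[AtomRecord]:
    """Assign polar-hydrogen parents and acceptor flags within each unit."""
    by_unit: dict[str, list[AtomRecord]] = {}
    for r in records:
        by_unit.setdefault(r.unit, []).append(r)
    for unit_records in by_unit.values():
        heavies = [r for r in unit_records if r.element != "H"]
        h_by_heavy: dict[str, int] = {}
        for r in unit_records:
            if r.element != "H":
                continue
            best, bd = None, 1.3
            for h in heavies:
                d = float(np.linalg.norm(r.coords - h.coords))
                if d < bd:
                    best, bd = h, d
            if best is not None and best.element in ("N", "O", "S"):
                r.polar_h_parent = best.name
                r.parent_coords = best.coords
                h_by_heavy[best.name] = h_by_heavy.get(best.name, 0) + 1
        for r in heavies:
            if r.element == "O":
                r.is_acceptor = True
            elif r.element == "N":
                r.is_acceptor = h_by_heavy.get(r.name, 0) == 0
    return records


class AtomRecords:
    """Vectorized view over a list of :class:`AtomRecord`."""

    def __init__(self, records: Sequence[AtomRecord]):
        self.records = list(records)
        n = len(self.records)
        self.coords = np.array([r.coords for r in self.records]).reshape(n, 3)
        self.radius = np.array([r.radius for r in self.records])
        self.charge = np.array([r.charge for r in self.records])
        self.is_h = np.array([r.element == "H" for r in self.records])
        self.polar_h = np.array([r.polar_h_parent is not None for r in self.records])
        self.acceptor = np.array([r.is_acceptor for r in self.records])
        self.parent_coords = np.array(
            [
                r.parent_coords if r.parent_coords is not None else np.zeros(3)
                for r in self.records
            ]
        ).reshape(n, 3)

    def __len__(self):
        return len(self.records)


def _exclusion_mask(A: AtomRecords, B: AtomRecords, excluded_pairs) -> Optional[np.ndarray]:
    if not excluded_pairs:
        return None
    excl = set(excluded_pairs)
    mask = np.zeros((len(A), len(B)), dtype=bool)
    ids_a = [r.atom_id for r in A.records]
    ids_b = [r.atom_id for r in B.records]
    for i, ia in enumerate(ids_a):
        for j, jb in enumerate(ids_b):
            if (ia, jb) in excl or (jb, ia) in excl:
                mask[i, j] = True
    return mask


def interaction_energy(
    A: AtomRecords | Sequence[AtomRecord],
    B: AtomRecords | Sequence[AtomRecord],
    params: EnergyParams = DEFAULT_ENERGY_PARAMS,
    excluded_pairs: Optional[Iterable[tuple]] = None,
) -> float:
    """Total interaction energy (PEU) between two disjoint atom groups."""
    if not isinstance(A, AtomRecords):
        A = AtomRecords(A)
    if not isinstance(B, AtomRecords):
        B = AtomRecords(B)
    if len(A) == 0 or len(B) == 0:
        return 0.0
    d = cdist(A.coords, B.coords)
    np.clip(d, 0.05, None, out=d)
    excl = _exclusion_mask(A, B, excluded_pairs)

    # --- van der Waals (skip polar-H/acceptor pairs; the H-bond term owns them)
    r0 = A.radius[:, None] + B.radius[None, :]
    onset = params.clash_onset * r0
    hb_pair = (A.polar_h[:, None] & B.acceptor[None, :]) | (
        A.acceptor[:, None] & B.polar_h[None, :]
    )
    vdw_mask = ~hb_pair
    if excl is not None:
        vdw_mask &= ~excl
    rep = np.where(
        (d < onset) & vdw_mask, params.k_rep * (onset - d) / onset, 0.0
    )
    att_region = (d >= onset) & (d <= params.vdw_cutoff) & vdw_mask
    att = np.where(att_region, -params.eps_att * (r0 / d) ** 6, 0.0)
    e_vdw = float(np.sum(rep) + np.sum(att))

    # --- electrostatics, eps(r) = slope * r
    qq = A.charge[:, None] * B.charge[None, :]
    e_pair = params.coulomb_k * qq / (params.dielectric_slope * d * d)
    np.clip(e_pair, -params.elec_cap, params.elec_cap, out=e_pair)
    elec_mask = d <= params.elec_cutoff
    if excl is not None:
        elec_mask &= ~excl
    e_elec = float(np.sum(np.where(elec_mask, e_pair, 0.0)))

    # --- directional 10-12 hydrogen bonds
    e_hb = _hbond_energy(A, B, d, params, excl) + _hbond_energy(
        B, A, d.T, params, excl.T if excl is not None else None
    )
    return e_vdw + e_elec + e_hb


def _hbond_energy(D: AtomRecords, Acc: AtomRecords, d, params, excl) -> float:
    hi = np.where(D.polar_h)[0]
    ai = np.where(Acc.acceptor)[0]
    if len(hi) == 0 or len(ai) == 0:
        return 0.0
    total = 0.0
    for i in hi:
        dj = d[i, ai]
        near = ai[dj <= params.hb_cutoff]
        for j in near:
            if excl is not None and excl[i, j]:
                continue
            u_hd = D.parent_coords[i] - D.coords[i]
            u_ha = Acc.coords[j] - D.coords[i]
            nu = np.linalg.norm(u_hd) * np.linalg.norm(u_ha)
            if nu < 1e-9:
                continue
            cos_t = float(np.dot(u_hd, u_ha) / nu)  # cos(D-H...A angle)
            f = max(0.0, -cos_t) ** 2
            if f == 0.0:
                continue
            x = params.r0_hb / max(d[i, j], 0.5)
            well = float(np.clip(5.0 * x**12 - 6.0 * x**10, -1.2, 3.0))
            total += params.eps_hb * well * f
    return total


@dataclass(frozen=True)
class HBond:
    donor_id: tuple[str, str]  # (unit, donor heavy-atom name)
    acceptor_id: tuple[str, str]
    distance: float  # donor heavy to acceptor heavy (A)
    angle: float  # D-H...A (deg)

    @property
    def key(self) -> tuple:
        return (self.donor_id, self.acceptor_id)


def detect_hydrogen_bonds(
    records: Sequence[AtomRecord],
    max_donor_acceptor: float = 3.3,
    min_angle: float = 120.0,
    include_intra_unit: bool = False,
) -> list[HBond]:
    """Geometric hydrogen-bond detection.

    A bond is reported when the donor-heavy to acceptor distance is at most
    ``max_donor_acceptor`` (closed interval) and the D-H...A angle is at least
    ``min_angle``.  Hydrogens must already be present.  Deterministic order.
    """
    recs = annotate_records(list(records))
    donors = [r for r in recs if r.polar_h_parent is not None]
    acceptors = [r for r in recs if r.is_acceptor]
    out: list[HBond] = []
    seen = set()
    for h in donors:
        for a in acceptors:
            if not include_intra_unit and a.unit == h.unit:
                continue
            if a.atom_id == (h.unit, h.polar_h_parent):
                continue
            d_da = float(np.linalg.norm(h.parent_coords - a.coords))
            if d_da > max_donor_acceptor + 1e-9:  # closed interval at the cutoff
                continue
            u_hd = h.parent_coords - h.coords
            u_ha = a.coords - h.coords
            nu = np.linalg.norm(u_hd) * np.linalg.norm(u_ha)
            if nu < 1e-9:
                continue
            theta = float(np.degrees(np.arccos(np.clip(np.dot(u_hd, u_ha) / nu, -1, 1))))
            if theta < min_angle:
                continue
            hb = HBond((h.unit, h.polar_h_parent), a.atom_id, d_da, theta)
            if hb.key in seen:
                continue
            seen.add(hb.key)
            out.append(hb)
    out.sort(key=lambda b: (b.donor_id, b.acceptor_id))
    return out
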