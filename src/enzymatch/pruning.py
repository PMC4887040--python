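"""Pruning strategies that keep active-site matching tractable.

Four stages, applied in order of increasing cost:

(i)   maximum-reach pruning of site pairs whose kinematic chain cannot span
      the inter-anchor CA distance;
(ii)  RMSD deduplication of converged loops (multistart solutions that found
      the same geometry);
(iii) immediate constraint checks on freshly closed loops (performed by the
      matching engine using the motif module);
(iv)  linear van-der-Waals repulsion thresholds between closed loops / whole
      matches and the scaffold backbone or template.

"Backbone" means the main-chain atoms of candidate-site residues; "template"
means all atoms of residues not at candidate sites.  Default thresholds are
150 PEU (main loop vs backbone), 30 PEU (side loop vs backbone), 200 PEU
(match vs template) and 50 PEU (match vs backbone), calibrated so planted
ground-truth matches always pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .closure import ClosedLoop
from .loops import KinematicLoop

__all__ = [
    "PruningParams",
    "RepulsionModel",
    "prune_by_reach",
    "dedup_loops",
    "repulsion_energy",
    "prune_by_repulsion",
]

STAGES = ("main_loop", "side_loop", "match_vs_template", "match_vs_backbone")


@dataclass(frozen=True)
class PruningParams:
    main_loop_backbone_max: float = 150.0  # PEU
    side_loop_backbone_max: float = 30.0
    match_template_max: float = 200.0
    match_backbone_max: float = 50.0
    dedup_rmsd: float = 0.5  # A
    reach_margin: float = 0.5  # A of slack added to the reach bound

    def threshold(self, stage: str) -> float:
        return {
            "main_loop": self.main_loop_backbone_max,
            "side_loop": self.side_loop_backbone_max,
            "match_vs_template": self.match_template_max,
            "match_vs_backbone": self.match_backbone_max,
        }[stage]


@dataclass(frozen=True)
class RepulsionModel:
    """Linear repulsive term: e(r) = k * max(0, c*(Ri+Rj) - r) / (c*(Ri+Rj))."""

    k: float = 10.0  # PEU per fully overlapping pair
    c: float = 0.85  # clash-onset fraction of the radius sum


DEFAULT_REPULSION = RepulsionModel()


def prune_by_reach(
    site_pair_ca: Sequence[np.ndarray],
    loop: KinematicLoop,
    params: PruningParams = PruningParams(),
    reach: Optional[float] = None,
) -> bool:
    """True = keep, False = prune.

    Prunes when the loop's maximum reach (plus margin) cannot span the true
    CA-CA distance of the anchoring site pair.  ``reach`` may be supplied to
    reuse a cached :func:`~enzymatch.closure.max_loop_length` result.
    """
    if reach is None:
        from .closure import max_loop_length

        reach = max_loop_length(loop)
    ca1, ca2 = (np.asarray(p, float) for p in site_pair_ca)
    return reach + params.reach_margin >= float(np.linalg.norm(ca1 - ca2))


def dedup_loops(closed: Sequence[ClosedLoop], threshold: float = 0.5) -> list[ClosedLoop]:
    """Greedy streaming deduplication in input order.

    A loop is kept iff its no-fit RMSD over placed atoms to every previously
    kept loop exceeds ``threshold``; output order is stable.
    """
    kept: list[ClosedLoop] = []
    kept_coords: list[np.ndarray] = []
    for loop in closed:
        coords = loop.coords
        dup = False
        for kc in kept_coords:
            rmsd = float(np.sqrt(np.mean(np.sum((coords - kc) ** 2, axis=1))))
            if rmsd <= threshold:
                dup = True
                break
        if not dup:
            kept.append(loop)
            kept_coords.append(coords)
    return kept


def repulsion_energy(
    atoms_a,
    atoms_b,
    model: RepulsionModel = DEFAULT_REPULSION,
) -> float:
    """Linear repulsive energy (PEU) between two disjoint heavy-atom groups.

    Atom groups are sequences of objects with ``coords`` and ``vdw_radius``
    (e.g. :class:`~enzymatch.structure.Atom`) or ``(coords, radius)`` pairs.
    """

    def _unpack(atoms):
        cs, rs = [], []
        for a in atoms:
            if hasattr(a, "coords"):
                if getattr(a, "vdw_radius", None) is None:
                    raise ValueError(f"atom {getattr(a, 'name', a)} has no vdW radius")
                cs.append(np.asarray(a.coords, float))
                rs.append(float(a.vdw_radius))
            else:
                c, r = a
                cs.append(np.asarray(c, float))
                rs.append(float(r))
        return np.array(cs).reshape(len(cs), 3), np.array(rs)

    ca, ra = _unpack(list(atoms_a))
    cb, rb = _unpack(list(atoms_b))
    if len(ca) == 0 or len(cb) == 0:
        return 0.0
    d = cdist(ca, cb)
    onset = model.c * (ra[:, None] + rb[None, :])
    e = np.where(d < onset, model.k * (onset - d) / onset, 0.0)
    return float(np.sum(e))


def prune_by_repulsion(
    stage: str, energy: float, params: PruningParams = PruningParams()
) -> bool:
    """True = keep, False = prune (energy exceeds the stage threshold)."""
    if stage not in STAGES:
        raise ValueError(f"unknown pruning stage {stage!r}")
    return energy <= params.threshold(stage)
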