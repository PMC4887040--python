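"""Scaffold-library filtering and multi-scaffold screening.

The library filter mirrors the standard construction of a design scaffold
set: X-ray structures below a resolution cutoff, size window on the residue
count, mutual sequence identity below a threshold (via precomputed identity
clusters), catalytic-annotation (CSA-style) membership and an expression
flag.  Screening runs the matching engine on every scaffold, centering
candidate-site selection on the scaffold's annotated catalytic residues
(15-A CA-centroid rule), and applies a burial proxy for the visual
TS-in-pocket inspection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import Match, MatchConfig, match_scaffold
from .motif import CatalyticMotif
from .structure import ProteinStructure, build_hydrogens, candidate_sites, read_structure

__all__ = [
    "LibraryCriteria",
    "filter_library",
    "pocket_check",
    "ScreenReport",
    "screen",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LibraryCriteria:
    require_xray: bool = True
    max_resolution: float = 3.0  # strict: resolution must be < this
    min_residues: int = 300
    max_residues: int = 800
    max_identity: float = 95.0  # % — enforced via identity clusters
    require_csa: bool = True
    require_ecoli_expression: bool = True

    def __post_init__(self):
        if self.min_residues > self.max_residues:
            raise ValueError("min_residues must be <= max_residues")
        if self.max_resolution <= 0:
            raise ValueError("max_resolution must be positive")


_REQUIRED_COLUMNS = ("id", "method", "resolution", "n_residues", "csa", "expression")


def filter_library(
    metadata: pd.DataFrame, criteria: LibraryCriteria = LibraryCriteria()
) -> tuple[list[str], dict[str, str]]:
    """Apply the library criteria; returns (kept ids, id -> drop reason).

    The identity filter keeps the first member (by id order) of each
    ``identity_cluster``; if the column is absent all entries are treated as
    mutually dissimilar.  Idempotent and order-stable.
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in metadata.columns]
    if missing:
        raise KeyError(f"metadata lacks required columns: {missing}")
    reasons: dict[str, str] = {}
    kept: list[str] = []
    seen_clusters: set = set()
    df = metadata.copy()
    if "identity_cluster" in df.columns:
        df = df.sort_values("id", kind="stable")
    for _, row in df.iterrows():
        sid = str(row["id"])
        if criteria.require_xray and str(row["method"]).upper() not in ("XRAY", "X-RAY", "X-RAY DIFFRACTION"):
            reasons[sid] = "method"
            continue
        if not (float(row["resolution"]) < criteria.max_resolution):
            reasons[sid] = "resolution"
            continue
        n = int(row["n_residues"])
        if not (criteria.min_residues <= n <= criteria.max_residues):
            reasons[sid] = "size"
            continue
        if criteria.require_csa and not bool(row["csa"]):
            reasons[sid] = "csa"
            continue
        if criteria.require_ecoli_expression and not bool(row["expression"]):
            reasons[sid] = "expression"
            continue
        if "identity_cluster" in df.columns:
            cl = row["identity_cluster"]
            if cl in seen_clusters:
                reasons[sid] = "identity"
                continue
            seen_clusters.add(cl)
        kept.append(sid)
    if "identity_cluster" in metadata.columns:
        order = {str(r["id"]): i for i, r in metadata.iterrows()}
        kept.sort(key=lambda s: order.get(s, 0))
    return kept, reasons


def pocket_check(
    match: Match,
    scaffold: ProteinStructure,
    min_buried_fraction: float = 0.6,
    neighbor_count: int = 8,
    neighbor_radius: float = 6.0,
) -> bool:
    """Burial proxy for the TS-inside-the-pocket inspection.

    Passes when at least ``min_buried_fraction`` of TS heavy atoms have at
    least ``neighbor_count`` protein heavy atoms within ``neighbor_radius``.
    """
    ts = np.array([x for n, x in match.ts_pose.items() if not n.startswith("H")])
    prot = scaffold.heavy_coords()
    if len(ts) == 0 or len(prot) == 0:
        return min_buried_fraction <= 0
    d2 = np.sum((ts[:, None, :] - prot[None, :, :]) ** 2, axis=-1)
    counts = np.sum(d2 <= neighbor_radius**2, axis=1)
    frac = float(np.mean(counts >= neighbor_count))
    return frac >= min_buried_fraction


@dataclass
class ScaffoldResult:
    scaffold_id: str
    n_matches: int
    discard_reason: Optional[str] = None  # None | "no-match" | "pocket-check-fail" | "error"
    top_matches: list[dict] = field(default_factory=list)


@dataclass
class ScreenReport:
    per_scaffold: list[ScaffoldResult]
    n_scaffolds: int = 0
    n_selected: int = 0
    n_discarded: int = 0
    n_errors: int = 0

    def __post_init__(self):
        self.n_scaffolds = len(self.per_scaffold)
        self.n_selected = sum(
            1 for r in self.per_scaffold if r.discard_reason is None and r.n_matches > 0
        )
        self.n_errors = sum(1 for r in self.per_scaffold if r.discard_reason == "error")
        self.n_discarded = self.n_scaffolds - self.n_selected
        assert self.n_selected + self.n_discarded == self.n_scaffolds

    def to_json(self) -> str:
        doc = {
            "summary": {
                "n_scaffolds": self.n_scaffolds,
                "n_selected": self.n_selected,
                "n_discarded": self.n_discarded,
                "n_errors": self.n_errors,
            },
            "per_scaffold": [asdict(r) for r in self.per_scaffold],
        }
        return json.dumps(doc, indent=2, sort_keys=True)


def _match_summary(m: Match, rank: int) -> dict:
    return {
        "rank": rank,
        "score": round(m.rank_score, 6),
        "assignment": m.assignment_labels(),
        "rms_constraint_deviation": round(m.constraint_report.rms_deviation, 6),
        "repulsion": {k: round(v, 3) for k, v in m.repulsion.items()},
    }


def _screen_one(
    pdb_path: Path,
    motif: CatalyticMotif,
    config: MatchConfig,
    catalytic: Sequence,
    pocket_fraction: float,
) -> ScaffoldResult:
    sid = pdb_path.stem
    try:
        scaffold = read_structure(pdb_path.read_text(), source_id=sid)
        build_hydrogens(scaffold)
        sites = candidate_sites(scaffold, catalytic, config.candidate_radius)
        matches = match_scaffold(scaffold, motif, config, sites=sites)
    except Exception as exc:
        logger.warning("scaffold %s failed: %s", sid, exc)
        return ScaffoldResult(sid, 0, discard_reason="error")
    if not matches:
        return ScaffoldResult(sid, 0, discard_reason="no-match")
    surviving = [
        m for m in matches
        if pocket_check(m, scaffold, min_buried_fraction=pocket_fraction)
    ]
    if not surviving:
        return ScaffoldResult(sid, 0, discard_reason="pocket-check-fail")
    return ScaffoldResult(
        sid,
        len(surviving),
        top_matches=[_match_summary(m, i + 1) for i, m in enumerate(surviving[:5])],
    )


def screen(
    library_dir,
    motif: CatalyticMotif,
    config: MatchConfig = MatchConfig(),
    annotations: Optional[dict[str, Sequence]] = None,
    pocket_fraction: float = 0.6,
    n_jobs: int = 1,
) -> ScreenReport:
    """Screen every ``*.pdb`` scaffold in a directory against a motif.

    Each scaffold needs a catalytic-residue annotation: either an entry in
    ``annotations`` (scaffold id -> residue id list) or a sidecar JSON file
    ``<stem>.csa.json`` with a ``catalytic_residues`` list.  Scaffolds are
    embarrassingly parallel (joblib) with a deterministic merge.
    """
    library_dir = Path(library_dir)
    pdbs = sorted(library_dir.glob("*.pdb"))
    jobs = []
    results: list[ScaffoldResult] = []
    for p in pdbs:
        cat = (annotations or {}).get(p.stem)
        if cat is None:
            sidecar = p.with_suffix(".csa.json")
            if sidecar.exists():
                cat = [tuple(x) for x in json.loads(sidecar.read_text())["catalytic_residues"]]
        if cat is None:
            logger.warning("scaffold %s has no catalytic annotation; skipped", p.stem)
            results.append(ScaffoldResult(p.stem, 0, discard_reason="error"))
            continue
        jobs.append((p, cat))
    if n_jobs > 1:
        from joblib import Parallel, delayed

        out = Parallel(n_jobs=n_jobs)(
            delayed(_screen_one)(p, motif, config, cat, pocket_fraction) for p, cat in jobs
        )
    else:
        out = [_screen_one(p, motif, config, cat, pocket_fraction) for p, cat in jobs]
    results.extend(out)
    results.sort(key=lambda r: r.scaffold_id)
    return ScreenReport(per_scaffold=results)
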