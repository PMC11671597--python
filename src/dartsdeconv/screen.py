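"""The DARTS candidate-selection cascade.

A drug-affinity responsive target stability (DARTS) experiment compares
sequence coverage in three conditions: an undigested control, a
pronase-digested arm, and a pronase-plus-drug arm. Candidate targets are
proteins that (i) are appreciably degraded by pronase — coverage drops from
control to pronase — and (ii) are protected by the drug — coverage rises
from pronase to pronase+drug. Survivors are ranked by the strength of the
protection.

Thresholds default to 5 absolute percentage points of coverage with strict
inequality for both filters; a relative-percent mode is available since
"more than 5%" admits either reading.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import CONDITIONS
from .errors import EvidenceError

STAT_COLUMNS = [
    "protein_id",
    "cov_control",
    "cov_pronase",
    "cov_drug",
    "degradation",
    "stabilization",
    "fold_change",
]


@dataclass(frozen=True)
class ScreenThresholds:
    """Filter thresholds, in coverage percentage points (or relative %)."""

    min_degradation: float = 5.0
    min_stabilization: float = 5.0
    strict: bool = True
    mode: str = "points"  # "points" (absolute coverage points) or "relative"

    def __post_init__(self) -> None:
        if self.min_degradation < 0 or self.min_stabilization < 0:
            raise EvidenceError("screen thresholds must be nonnegative")
        if self.mode not in ("points", "relative"):
            raise EvidenceError(f"unknown screen mode {self.mode!r}")


def compute_screen_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a coverage table into per-protein triplets with derived stats.

    degradation   = cov_control - cov_pronase
    stabilization = cov_drug    - cov_pronase
    fold_change   = cov_drug / cov_pronase  (NaN when cov_pronase == 0)
    """
    wide = table.pivot(index="protein_id", columns="condition", values="coverage")
    missing = [c for c in CONDITIONS if c not in wide.columns]
    if missing:
        raise EvidenceError(f"coverage table lacks conditions: {missing}")
    incomplete = wide.index[wide[list(CONDITIONS)].isna().any(axis=1)]
    if len(incomplete):
        raise EvidenceError(
            f"proteins missing a condition: {sorted(incomplete.tolist())}"
        )
    stats = pd.DataFrame(
        {
            "protein_id": wide.index,
            "cov_control": wide["control"].to_numpy(),
            "cov_pronase": wide["pronase"].to_numpy(),
            "cov_drug": wide["pronase_drug"].to_numpy(),
        }
    )
    stats["degradation"] = stats["cov_control"] - stats["cov_pronase"]
    stats["stabilization"] = stats["cov_drug"] - stats["cov_pronase"]
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = stats["cov_drug"] / stats["cov_pronase"]
    stats["fold_change"] = fc.where(stats["cov_pronase"] > 0, np.nan)
    return stats.reset_index(drop=True)


def _deltas(stats: pd.DataFrame, mode: str) -> tuple[pd.Series, pd.Series]:
    if mode == "points":
        return stats["degradation"], stats["stabilization"]
    # relative percent change; zero denominators never pass the filter
    with np.errstate(divide="ignore", invalid="ignore"):
        deg = 100.0 * stats["degradation"] / stats["cov_control"]
        stab = 100.0 * stats["stabilization"] / stats["cov_pronase"]
    return (
        deg.where(stats["cov_control"] > 0, -np.inf),
        stab.where(stats["cov_pronase"] > 0, -np.inf),
    )


def screen_candidates(
    stats: pd.DataFrame,
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the degradation and stabilization filters and rank survivors.

    Returns the ranked candidate table (with a 1-based ``rank`` column) and
    the cascade counts {total, degraded, candidates}. Ranking is by
    descending stabilization, then descending fold change, then protein id.
    """
    deg, stab = _deltas(stats, thresholds.mode)
    if thresholds.strict:
        degraded_mask = deg > thresholds.min_degradation
        stabilized_mask = stab > thresholds.min_stabilization
    else:
        degraded_mask = deg >= thresholds.min_degradation
        stabilized_mask = stab >= thresholds.min_stabilization
    candidate_mask = degraded_mask & stabilized_mask
    candidates = stats.loc[candidate_mask].copy()
    candidates["_fc_key"] = candidates["fold_change"].fillna(-np.inf)
    candidates = candidates.sort_values(
        ["stabilization", "_fc_key", "protein_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).drop(columns="_fc_key")
    candidates["rank"] = np.arange(1, len(candidates) + 1)
    cascade = {
        "total": int(len(stats)),
        "degraded": int(degraded_mask.sum()),
        "candidates": int(candidate_mask.sum()),
    }
    return candidates.reset_index(drop=True), cascade


def export_heatmap_matrix(
    stats: pd.DataFrame,
    candidates: pd.DataFrame,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Candidate x condition matrix of raw coverages, row-ordered by rank."""
    if stats.empty:
        raise EvidenceError("cannot export a heatmap from empty screen stats")
    cols = {"cov_control": "control", "cov_pronase": "pronase", "cov_drug": "pronase_drug"}
    matrix = (
        candidates.sort_values("rank")
        .set_index("protein_id")[list(cols)]
        .rename(columns=cols)
    )
    matrix.index.name = "protein_id"
    if path is not None:
        matrix.to_csv(path)
    return matrix
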