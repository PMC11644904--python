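"""Stage impairment scoring and baseline normalization.

A MATB subtask is "impaired" in a stage when its score shows an adverse
change (decrease) of at least the threshold fraction (default 30%) from
the subject's air-breathing resting baseline.  The stage impairment score
is the 0-4 count of impaired subtasks; the binary label collapses 1-4
into "impaired".  HRV features are normalized to percent change from the
same baseline stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .synth import BASELINE_GROUP, SUBTASKS

__all__ = [
    "subtask_flags",
    "stage_score",
    "score_cohort",
    "threshold_sensitivity",
    "percent_change",
]

_EPS = 1e-12


def subtask_flags(
    scores: np.ndarray, baseline: np.ndarray, threshold: float = 0.30
) -> np.ndarray:
    """Binary impairment flags: fractional decrease >= threshold (inclusive)."""
    scores = np.asarray(scores, float)
    baseline = np.asarray(baseline, float)
    if np.any(baseline <= 0):
        raise ValueError("baseline subtask scores must be positive")
    decrement = (baseline - scores) / baseline
    return (decrement >= threshold - _EPS).astype(int)


def stage_score(flags: np.ndarray) -> tuple[int, int]:
    """(stage impairment score 0-4, binary impaired indicator)."""
    flags = np.asarray(flags)
    if len(flags) != len(SUBTASKS):
        raise ValueError(f"expected {len(SUBTASKS)} flags")
    score = int(flags.sum())
    return score, int(score >= 1)


def _baseline_rows(matb: pd.DataFrame) -> pd.DataFrame:
    base = matb[matb["group_label"] == BASELINE_GROUP]
    if base.empty:
        raise ValueError(f"no baseline stage ({BASELINE_GROUP}) in cohort")
    return base.set_index("subject_id")


def score_cohort(matb: pd.DataFrame, threshold: float = 0.30) -> pd.DataFrame:
    """Impairment table: per-subtask flags, 0-4 score, binary label.

    Baseline is each subject's observed air-rest stage.  Stages with any
    missing subtask score, and subjects without a baseline stage, are
    dropped.
    """
    base = _baseline_rows(matb)
    rows = []
    for _, r in matb.iterrows():
        if r["subject_id"] not in base.index:
            continue
        b = base.loc[r["subject_id"]]
        svals = np.array([r[s] for s in SUBTASKS], float)
        bvals = np.array([b[s] for s in SUBTASKS], float)
        if np.any(~np.isfinite(svals)) or np.any(~np.isfinite(bvals)):
            continue
        flags = subtask_flags(svals, bvals, threshold)
        score, binary = stage_score(flags)
        row = {
            "subject_id": r["subject_id"],
            "stage_id": r["stage_id"],
            "score": score,
            "binary": binary,
        }
        for k, s in enumerate(SUBTASKS):
            row[f"flag_{s}"] = int(flags[k])
        rows.append(row)
    return pd.DataFrame(rows)


def threshold_sensitivity(
    matb: pd.DataFrame, thresholds: tuple[float, ...] = (0.15, 0.30, 0.45)
) -> pd.DataFrame:
    """R^2 of each subtask score against the stage impairment score.

    For each candidate threshold, the stage impairment score is recomputed
    and each subtask's continuous score is regressed on it across stages;
    the per-subtask R^2 and their mean quantify how well the discrete
    score summarizes the continuous performance data.
    """
    rows = []
    for thr in thresholds:
        imp = score_cohort(matb, threshold=thr)
        merged = matb.merge(imp[["stage_id", "score"]], on="stage_id")
        row = {"threshold": thr}
        r2s = []
        for s in SUBTASKS:
            if merged["score"].nunique() < 2:
                row[f"r2_{s}"] = float("nan")
                continue
            res = stats.linregress(merged["score"], merged[s])
            row[f"r2_{s}"] = res.rvalue**2
            r2s.append(res.rvalue**2)
        row["r2_mean"] = float(np.mean(r2s)) if r2s else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def percent_change(
    features: pd.DataFrame,
    feature_cols: list[str],
    baseline_stage: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Express features as percent change from the subject baseline stage.

    100 * (value - baseline) / |baseline|; the absolute-value denominator
    preserves the direction of change for negative baselines.  Features
    with a zero baseline become NaN rather than +/-inf.  The baseline
    stage itself normalizes to 0% wherever defined.
    """
    if baseline_stage is None:
        baseline_stage = features[features["group_label"] == BASELINE_GROUP]
    if baseline_stage.empty:
        raise ValueError("no baseline stage present")
    base = baseline_stage.set_index("subject_id")[feature_cols]
    out = features.copy()
    vals = features[feature_cols].to_numpy(float)
    bvals = base.reindex(features["subject_id"])[feature_cols].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (vals - bvals) / np.abs(bvals)
    pct[bvals == 0] = np.nan
    out[feature_cols] = pct
    return out
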