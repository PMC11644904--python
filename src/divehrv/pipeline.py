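"""End-to-end feature extraction: NN series or ECG -> 25-feature row.

Ties the preprocessing chain to the three feature families and assembles
per-cohort feature tables joined with exposure covariates and impairment
labels, ready for the association and ML modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import EcgRecord, NNSeries
from .features_pdm import PDM_FEATURES, PdmConfig, pdm_features
from .features_spectral import SPECTRAL_FEATURES, SpectralConfig, spectral_features
from .features_time import TIME_DOMAIN_FEATURES, time_domain_features
from .impairment import percent_change, score_cohort
from .preprocess import UnanalyzableStageError, berger_hr, ecg_to_nn, to_analysis_series
from .synth import Cohort

__all__ = [
    "ALL_FEATURES",
    "extract_stage_features",
    "extract_stage_features_from_ecg",
    "cohort_features",
    "analysis_frame",
]

ALL_FEATURES = TIME_DOMAIN_FEATURES + SPECTRAL_FEATURES + PDM_FEATURES


def extract_stage_features(
    nn: NNSeries,
    washin_s: float = 90.0,
    stage_len_s: float = 300.0,
    spectral_cfg: SpectralConfig | None = None,
    pdm_cfg: PdmConfig | None = None,
) -> dict:
    """All 25 HRV features for one stage from a cleaned NN series.

    Time-domain features use the NN intervals inside the analysis window;
    spectral and PDM features use the Berger-resampled, detrended HR
    series (1 Hz; PowerRatio from the 4 Hz series).
    """
    hr4 = berger_hr(nn, fs_out=4.0)
    hr1 = to_analysis_series(hr4, washin_s=washin_s, stage_len_s=stage_len_s)
    # restrict the NN list to the same analysis window
    mask = (nn.interval_times >= washin_s) & (nn.interval_times < stage_len_s)
    nn_win = NNSeries(
        intervals=nn.intervals[mask], interval_times=nn.interval_times[mask]
    )
    feats = time_domain_features(nn_win, hr1)
    # 4 Hz series trimmed to the analysis window for PowerRatio
    t4 = hr4.times
    m4 = (t4 >= washin_s) & (t4 < stage_len_s)
    hr4_win = type(hr4)(values=hr4.values[m4], fs=hr4.fs, t0=washin_s)
    feats.update(spectral_features(hr1, hr4_win, spectral_cfg))
    pdm = pdm_features(hr1, pdm_cfg)
    feats["Symp"] = pdm["Symp"]
    feats["PSymp"] = pdm["PSymp"]
    return feats


def extract_stage_features_from_ecg(ecg: EcgRecord, **kwargs) -> dict:
    """Condition an ECG trace and extract the 25 features."""
    nn = ecg_to_nn(ecg)
    return extract_stage_features(nn, **kwargs)


def cohort_features(
    cohort: Cohort, washin_s: float = 90.0, stage_len_s: float = 300.0
) -> pd.DataFrame:
    """Per-stage feature table for a simulated cohort.

    Stages that fail preprocessing are skipped (mirroring the exclusion
    of technically failed stages).
    """
    rows = []
    meta = cohort.stages.set_index("stage_id")
    for stage_id, nn in cohort.nn.items():
        try:
            feats = extract_stage_features(
                nn, washin_s=washin_s, stage_len_s=stage_len_s
            )
        except (UnanalyzableStageError, ValueError):
            continue
        rec = meta.loc[stage_id]
        row = {
            "subject_id": rec["subject_id"],
            "stage_id": stage_id,
            "group_label": rec["group_label"],
            "exercise": int(rec["exercise"]),
            "high_n2": int(rec["high_n2"]),
            "high_co2": int(rec["high_co2"]),
            "high_o2": int(rec["high_o2"]),
        }
        row.update(feats)
        rows.append(row)
    return pd.DataFrame(rows)


def analysis_frame(
    cohort: Cohort,
    threshold: float = 0.30,
    washin_s: float = 90.0,
    stage_len_s: float = 300.0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Features + impairment labels, features as % change from baseline.

    The returned frame has one row per analyzable stage with the 25 HRV
    features (percent change from the subject's air-rest baseline when
    ``normalize``), the exposure covariates, the 0-4 stage impairment
    score and the binary impaired label.
    """
    feats = cohort_features(cohort, washin_s=washin_s, stage_len_s=stage_len_s)
    if normalize:
        feats = percent_change(feats, ALL_FEATURES)
    imp = score_cohort(cohort.matb, threshold=threshold)
    merged = feats.merge(
        imp[["stage_id", "score", "binary"]], on="stage_id", how="inner"
    )
    return merged
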