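"""Time-domain HRV features.

Fifteen features computed from the cleaned NN-interval list (summary
statistics, the NN50 family, Poincare geometry, approximate entropy) and,
for the AR(2) features, from the evenly sampled 1 Hz detrended HR series.

Conventions:
 * NN50count1 counts successive *lengthenings* by more than the threshold,
   NN50count2 counts *shortenings*, NN50count is their sum ("more than
   50 ms" is strict).
 * SD1/SD2 are the dispersions of the rotated lag-1 Poincare plot with
   sample (n-1) variance, so SD1 == RMSSD/sqrt(2) exactly at lag 1.
 * Approximate entropy follows Pincus: m = 2, r = 0.2 * SD, Chebyshev
   distance, self-matches included.
 * AR(2) is fitted by the Burg method; AR_noise_var is the innovation
   variance normalized by the signal variance.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from statsmodels.regression.linear_model import burg

from .containers import HrSignal, NNSeries

__all__ = [
    "TIME_DOMAIN_FEATURES",
    "summary_stats",
    "successive_diff_family",
    "poincare",
    "approx_entropy",
    "ar2_fit",
    "time_domain_features",
]

TIME_DOMAIN_FEATURES = [
    "AE",
    "AR_1",
    "AR_2",
    "AR_noise_var",
    "meanHR",
    "meanNN",
    "NN50count",
    "NN50count1",
    "NN50count2",
    "pNN50",
    "r_RR",
    "RMSSD",
    "SD1",
    "SD2",
    "SDNN",
]


def summary_stats(nn: NNSeries) -> tuple[float, float, float]:
    """Return (meanNN ms, meanHR bpm, SDNN ms)."""
    x = nn.intervals
    if len(x) < 2:
        raise ValueError("need at least 2 intervals")
    mean_nn = float(np.mean(x))
    return mean_nn, 60000.0 / mean_nn, float(np.std(x, ddof=1))


def successive_diff_family(
    nn: NNSeries, threshold_ms: float = 50.0
) -> tuple[float, int, int, int, float]:
    """Return (RMSSD, NN50count, NN50count1, NN50count2, pNN50)."""
    x = nn.intervals
    if len(x) < 2:
        raise ValueError("need at least 2 intervals")
    d = np.diff(x)
    rmssd = float(np.sqrt(np.mean(d**2)))
    n1 = int(np.sum(d > threshold_ms))
    n2 = int(np.sum(d < -threshold_ms))
    pnn = 100.0 * (n1 + n2) / (len(x) - 1)
    return rmssd, n1 + n2, n1, n2, pnn


def poincare(nn: NNSeries, lag: int = 1) -> tuple[float, float, float]:
    """Poincare plot dispersions and correlation at the given beat lag.

    SD1 is the dispersion across the identity line (short-term
    variability), SD2 along it.  r_RR is the Pearson correlation of the
    lagged pairs; NaN for a zero-variance series.
    """
    x = nn.intervals
    if len(x) < lag + 2:
        raise ValueError("need at least lag + 2 intervals")
    a, b = x[:-lag], x[lag:]
    # SD1 without mean subtraction so SD1 == RMSSD/sqrt(2) holds exactly
    # at lag 1 (the mean successive difference telescopes to near zero
    # but not exactly zero)
    sd1 = float(np.sqrt(np.mean((a - b) ** 2) / 2.0))
    sd2 = float(np.std((a + b) / np.sqrt(2), ddof=1))
    if np.std(a) == 0 or np.std(b) == 0:
        return sd1, sd2, float("nan")
    r = float(np.corrcoef(a, b)[0, 1])
    return sd1, sd2, r


def approx_entropy(series: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """Pincus approximate entropy ApEn(m, r) with r = r_frac * SD.

    Phi_m - Phi_{m+1} with Chebyshev distance and self-matches included.
    Zero for a constant series.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 10 * m:
        raise ValueError("series too short for the chosen embedding")
    sd = np.std(x)
    if sd == 0:
        return 0.0
    r = r_frac * sd

    def phi(mm: int) -> float:
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = cdist(emb, emb, metric="chebyshev")
        c = np.mean(d <= r, axis=1)
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def ar2_fit(hr1: HrSignal) -> tuple[float, float, float]:
    """Burg AR(2) fit of the detrended 1 Hz HR series.

    Returns (a1, a2, normalized innovation variance) for the model
    x_t = a1*x_{t-1} + a2*x_{t-2} + e_t.  NaNs if the fit is degenerate.
    """
    x = np.asarray(hr1.values, dtype=float)
    if len(x) < 20:
        raise ValueError("need at least 20 samples")
    var = float(np.var(x))
    if var == 0:
        return float("nan"), float("nan"), float("nan")
    rho, sigma2 = burg(x, order=2, demean=True)
    a1, a2 = float(rho[0]), float(rho[1])
    nvar = float(sigma2) / var
    if not (np.isfinite(a1) and np.isfinite(a2) and np.isfinite(nvar)):
        return float("nan"), float("nan"), float("nan")
    return a1, a2, nvar


def time_domain_features(
    nn: NNSeries,
    hr1: HrSignal,
    nn50_threshold_ms: float = 50.0,
    poincare_lag: int = 1,
    apen_m: int = 2,
    apen_r_frac: float = 0.2,
) -> dict:
    """All 15 time-domain features as a name -> value mapping."""
    mean_nn, mean_hr, sdnn = summary_stats(nn)
    rmssd, n50, n50_1, n50_2, pnn50 = successive_diff_family(nn, nn50_threshold_ms)
    sd1, sd2, r_rr = poincare(nn, poincare_lag)
    ae = approx_entropy(nn.intervals, m=apen_m, r_frac=apen_r_frac)
    a1, a2, nvar = ar2_fit(hr1)
    return {
        "AE": ae,
        "AR_1": a1,
        "AR_2": a2,
        "AR_noise_var": nvar,
        "meanHR": mean_hr,
        "meanNN": mean_nn,
        "NN50count": n50,
        "NN50count1": n50_1,
        "NN50count2": n50_2,
        "pNN50": pnn50,
        "r_RR": r_rr,
        "RMSSD": rmssd,
        "SD1": sd1,
        "SD2": sd2,
        "SDNN": sdnn,
    }
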