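"""Power-spectral-density HRV features via the Welch periodogram.

The estimator uses 128-point segments with a Hann taper and 50% overlap,
giving a 1/128 = 0.0078125 Hz bin spacing on the 1 Hz HR series.  Band
powers are trapezoidal integrals over half-open bands with the exact band
edges interpolated, so adjacent bands tile the spectrum exactly
(VLF + LF + HF + residual == total power to machine precision).

PowerRatio (power below vs above 0.6 Hz) is computed on the 4 Hz Berger
series, whose 2 Hz Nyquist actually contains the 0.6-2 Hz band; the 1 Hz
series cannot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import HrSignal

__all__ = [
    "SPECTRAL_FEATURES",
    "SpectralConfig",
    "welch_psd",
    "band_power",
    "band_features",
    "power_ratio",
    "spectral_features",
]

SPECTRAL_FEATURES = ["VLF", "LF", "HF", "LFnu", "HFnu", "LF_HF", "PowerRatio", "total_psd"]


@dataclass
class SpectralConfig:
    """Welch configuration and band definitions."""

    nfft: int = 128
    window: str = "hann"
    overlap: float = 0.5
    vlf_band: tuple[float, float] = (0.0, 0.04)
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.4)
    split_freq: float = 0.6  # PowerRatio split on the 4 Hz series

    def __post_init__(self) -> None:
        if self.nfft & (self.nfft - 1):
            raise ValueError("nfft must be a power of two")
        if not (
            self.vlf_band[1] == self.lf_band[0] and self.lf_band[1] == self.hf_band[0]
        ):
            raise ValueError("bands must be contiguous and non-overlapping")


def welch_psd(
    x: HrSignal, cfg: SpectralConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD (freqs Hz, density) of an HR signal.

    Density scaling: the integral over (0, fs/2] approximates the signal
    variance (Parseval, window-power corrected by scipy).  Series shorter
    than one segment are refused rather than silently zero-padded.
    """
    cfg = cfg or SpectralConfig()
    v = np.asarray(x.values, dtype=float)
    if len(v) < cfg.nfft:
        raise ValueError(
            f"series length {len(v)} < nfft {cfg.nfft}; refusing to zero-pad"
        )
    freqs, psd = signal.welch(
        v,
        fs=x.fs,
        window=cfg.window,
        nperseg=cfg.nfft,
        noverlap=int(cfg.overlap * cfg.nfft),
        detrend="linear",
        scaling="density",
    )
    return freqs, psd


def band_power(
    freqs: np.ndarray, psd: np.ndarray, low: float, high: float
) -> float:
    """Trapezoidal band power over [low, high] with interpolated edges.

    Using the exact edges (linearly interpolated between bins) makes band
    powers additive across adjacent bands.
    """
    low = max(low, float(freqs[0]))
    high = min(high, float(freqs[-1]))
    if high <= low:
        return 0.0
    inner = freqs[(freqs > low) & (freqs < high)]
    f = np.concatenate([[low], inner, [high]])
    p = np.interp(f, freqs, psd)
    return float(np.trapezoid(p, f))


def band_features(
    freqs: np.ndarray, psd: np.ndarray, cfg: SpectralConfig | None = None
) -> dict:
    """VLF/LF/HF band powers, normalized units, LF/HF ratio, total power."""
    cfg = cfg or SpectralConfig()
    vlf = band_power(freqs, psd, *cfg.vlf_band)
    lf = band_power(freqs, psd, *cfg.lf_band)
    hf = band_power(freqs, psd, *cfg.hf_band)
    total = band_power(freqs, psd, float(freqs[0]), float(freqs[-1]))
    denom = lf + hf
    lfnu = lf / denom if denom > 0 else float("nan")
    hfnu = hf / denom if denom > 0 else float("nan")
    lf_hf = lf / hf if hf > 0 else float("nan")
    return {
        "VLF": vlf,
        "LF": lf,
        "HF": hf,
        "LFnu": lfnu,
        "HFnu": hfnu,
        "LF_HF": lf_hf,
        "total_psd": total,
    }


def power_ratio(hr4: HrSignal, cfg: SpectralConfig | None = None) -> float:
    """Ratio of spectral power below vs above the split frequency (0.6 Hz).

    Requires the 4 Hz series (Nyquist 2 Hz).  NaN when the denominator
    band is empty.
    """
    cfg = cfg or SpectralConfig()
    if hr4.fs <= 2 * cfg.split_freq:
        raise ValueError(
            f"PowerRatio needs fs > {2 * cfg.split_freq} Hz (got {hr4.fs})"
        )
    freqs, psd = welch_psd(hr4, cfg)
    num = band_power(freqs, psd, float(freqs[0]), cfg.split_freq)
    den = band_power(freqs, psd, cfg.split_freq, float(freqs[-1]))
    if den <= 0:
        return float("nan")
    return num / den


def spectral_features(
    hr1: HrSignal, hr4: HrSignal | None = None, cfg: SpectralConfig | None = None
) -> dict:
    """All 8 spectral features; PowerRatio is NaN without the 4 Hz series."""
    cfg = cfg or SpectralConfig()
    freqs, psd = welch_psd(hr1, cfg)
    feats = band_features(freqs, psd, cfg)
    feats["PowerRatio"] = power_ratio(hr4, cfg) if hr4 is not None else float("nan")
    return feats
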