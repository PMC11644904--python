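"""ECG conditioning and instantaneous-heart-rate construction.

Raw ECG -> baseline removal (moving-window median) -> band-pass denoising
-> adaptive-threshold R-peak detection with sub-sample refinement ->
artifact-screened NN intervals -> Berger 4 Hz instantaneous HR -> 1 Hz
detrended analysis series.

All operations are deterministic.  The denoiser is a zero-phase band-pass
filter and the detector an adaptive amplitude-threshold peak finder; both
are validated against synthetic ground truth (peak recovery within one
sample period).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .containers import EcgRecord, HrSignal, NNSeries, RPeakSeries

__all__ = [
    "UnanalyzableStageError",
    "remove_baseline",
    "denoise",
    "detect_r_peaks",
    "clean_nn",
    "berger_hr",
    "to_analysis_series",
    "ecg_to_nn",
    "read_ecg_csv",
]

#: physiologic NN bounds (ms): 30-220 bpm
NN_MIN_MS = 270.0
NN_MAX_MS = 2000.0
#: refractory period between R peaks (s)
REFRACTORY_S = 0.27


class UnanalyzableStageError(ValueError):
    """Raised when a stage cannot yield a usable NN series."""


def read_ecg_csv(path, subject_id: str = "", stage_id: str = "") -> EcgRecord:
    """Read a two-column ``time_s,mv`` CSV into an :class:`EcgRecord`."""
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(float)
    fs = 1.0 / np.median(np.diff(t))
    return EcgRecord(
        samples=df.iloc[:, 1].to_numpy(float),
        fs=float(round(fs, 6)),
        subject_id=subject_id,
        stage_id=stage_id,
        t0=float(t[0]),
    )


def remove_baseline(ecg: EcgRecord, window_s: float = 0.6) -> EcgRecord:
    """Subtract a running median to remove DC offset and slow drift.

    The window shrinks at the edges (nearest-sample padding), so no
    samples are lost.  Drift below roughly 1/window_s Hz is suppressed
    while narrow spikes (the R waves) pass almost untouched.
    """
    w = int(round(window_s * ecg.fs))
    if w < 3:
        raise ValueError("window must span at least 3 samples")
    if w > len(ecg.samples):
        raise ValueError("baseline window longer than record")
    if w % 2 == 0:
        w += 1
    baseline = ndimage.median_filter(ecg.samples, size=w, mode="nearest")
    return EcgRecord(
        samples=ecg.samples - baseline,
        fs=ecg.fs,
        subject_id=ecg.subject_id,
        stage_id=ecg.stage_id,
        t0=ecg.t0,
    )


def denoise(ecg: EcgRecord, band: tuple[float, float] = (0.5, 40.0)) -> EcgRecord:
    """Zero-phase Butterworth band-pass; upper edge clipped to 0.9*fs/2."""
    low, high = band
    high = min(high, 0.9 * ecg.fs / 2)
    if not 0 < low < high < ecg.fs / 2:
        raise ValueError(f"invalid band ({low}, {high}) for fs={ecg.fs}")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=ecg.fs, output="sos")
    return EcgRecord(
        samples=signal.sosfiltfilt(sos, ecg.samples),
        fs=ecg.fs,
        subject_id=ecg.subject_id,
        stage_id=ecg.stage_id,
        t0=ecg.t0,
    )


def _parabolic_offset(y0: float, y1: float, y2: float) -> float:
    """Sub-sample offset of the vertex of the parabola through 3 points."""
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))


def detect_r_peaks(ecg: EcgRecord, refine: bool = True) -> RPeakSeries:
    """Adaptive-threshold R-peak detection.

    The amplitude threshold is half the median of 2-second block maxima of
    the conditioned signal, so it tracks the prevailing R amplitude rather
    than any fixed voltage.  A 0.27 s refractory period enforces
    physiologic spacing; parabolic interpolation refines peak times below
    the sampling period (important at 100 Hz, where quantization alone is
    10 ms).
    """
    x = ecg.samples
    if len(x) < 3 or np.std(x) < 1e-12:
        raise UnanalyzableStageError("unanalyzable stage: flat or empty signal")
    block = max(1, int(round(2.0 * ecg.fs)))
    nblk = len(x) // block
    if nblk >= 1:
        maxima = x[: nblk * block].reshape(nblk, block).max(axis=1)
        thr = 0.5 * float(np.median(maxima))
    else:
        thr = 0.5 * float(np.max(x))
    if thr <= 0:
        raise UnanalyzableStageError("unanalyzable stage: no positive deflections")
    idx, _ = signal.find_peaks(
        x, height=thr, distance=max(1, int(round(REFRACTORY_S * ecg.fs)))
    )
    if len(idx) < 3:
        raise UnanalyzableStageError("unanalyzable stage: fewer than 3 R peaks")
    times = idx.astype(float)
    if refine:
        interior = (idx > 0) & (idx < len(x) - 1)
        offs = np.zeros(len(idx))
        for k in np.flatnonzero(interior):
            i = idx[k]
            offs[k] = _parabolic_offset(x[i - 1], x[i], x[i + 1])
        times = times + offs
    return RPeakSeries(peak_times=ecg.t0 + times / ecg.fs)


def clean_nn(peaks: RPeakSeries, max_reject_frac: float = 0.20) -> NNSeries:
    """Screen RR intervals for artifacts and interpolate rejected ones.

    An interval is rejected when it falls outside the physiologic range
    [270, 2000] ms or deviates from the running 5-beat median by more than
    30%.  Rejected intervals are replaced by interpolation over the local
    median of accepted neighbours.  If more than ``max_reject_frac`` of
    intervals are rejected the stage is declared unanalyzable, mirroring
    the exclusion of technically failed stages.
    """
    if len(peaks) < 3:
        raise UnanalyzableStageError("unanalyzable stage: fewer than 3 peaks")
    rr = np.diff(peaks.peak_times) * 1000.0
    runmed = ndimage.median_filter(rr, size=5, mode="nearest")
    bad = (rr < NN_MIN_MS) | (rr > NN_MAX_MS) | (np.abs(rr - runmed) > 0.30 * runmed)
    if bad.mean() > max_reject_frac:
        raise UnanalyzableStageError(
            f"unanalyzable stage: {100 * bad.mean():.0f}% of intervals rejected"
        )
    out = rr.copy()
    if bad.any():
        good = ~bad
        med_good = ndimage.median_filter(rr[good], size=5, mode="nearest")
        out[bad] = np.interp(
            np.flatnonzero(bad), np.flatnonzero(good), med_good
        )
        quality = np.where(bad, "corrected", "auto").astype(object)
    else:
        quality = np.array(["auto"] * len(rr), dtype=object)
    peaks.quality = np.concatenate([["auto"], quality])
    return NNSeries(intervals=out, interval_times=peaks.peak_times[1:])


def berger_hr(nn: NNSeries, fs_out: float = 4.0) -> HrSignal:
    """Berger windowed resampling of beat times to instantaneous HR (bpm).

    For each output sample a window of width 2/fs_out is centered on it;
    the fractional number of RR intervals overlapping the window, scaled
    by fs_out/2, gives the local rate.  Constant RR maps to exactly
    constant HR.
    """
    if len(nn) < 2:
        raise ValueError("need at least 2 intervals")
    beats = nn.beat_times
    # cumulative beat-count function: piecewise linear, slope 1/RR inside
    # each interval
    counts = np.arange(len(beats), dtype=float)
    half = 1.0 / fs_out
    t_start = beats[0] + half
    t_end = beats[-1] - half
    if t_end <= t_start:
        raise ValueError("record too short for Berger resampling")
    n_out = int(np.floor((t_end - t_start) * fs_out)) + 1
    t = t_start + np.arange(n_out) / fs_out
    n_hi = np.interp(t + half, beats, counts)
    n_lo = np.interp(t - half, beats, counts)
    hr = 60.0 * (n_hi - n_lo) * fs_out / 2.0
    return HrSignal(values=hr, fs=fs_out, detrended=False, t0=float(t[0]))


def to_analysis_series(
    hr4: HrSignal,
    washin_s: float = 90.0,
    stage_len_s: float = 300.0,
    detrend_cutoff_hz: float = 0.01,
    fs_out: float = 1.0,
) -> HrSignal:
    """Build the 1 Hz detrended analysis series.

    Discards the gas wash-in interval, anti-alias decimates to 1 Hz,
    removes trends below ``detrend_cutoff_hz`` (drift, but not the VLF
    band above 0.01 Hz) and subtracts the mean.  A 300 s stage with a
    90 s wash-in yields a 210-sample series.
    """
    if stage_len_s - washin_s < 60.0:
        raise ValueError("analysis window shorter than 60 s")
    t = hr4.times
    mask = (t >= washin_s) & (t < stage_len_s)
    x = hr4.values[mask]
    if len(x) < 60.0 * hr4.fs:
        raise ValueError("analysis window shorter than 60 s after wash-in")
    factor = int(round(hr4.fs / fs_out))
    if factor > 1:
        # zero-phase anti-alias low-pass, then stride; odd-extension
        # padding keeps constant signals exactly constant at the edges
        sos_aa = signal.butter(6, 0.45 * fs_out, btype="lowpass", fs=hr4.fs, output="sos")
        x = signal.sosfiltfilt(sos_aa, x)[::factor]
    if detrend_cutoff_hz > 0:
        sos = signal.butter(2, detrend_cutoff_hz, btype="highpass", fs=fs_out, output="sos")
        x = signal.sosfiltfilt(sos, x)
    x = x - x.mean()
    return HrSignal(values=x, fs=fs_out, detrended=True, t0=washin_s)


def ecg_to_nn(
    ecg: EcgRecord,
    baseline_window_s: float = 0.6,
    band: tuple[float, float] = (0.5, 40.0),
    refine: bool = True,
) -> NNSeries:
    """Full conditioning chain: baseline removal, denoise, detect, clean."""
    x = remove_baseline(ecg, baseline_window_s)
    x = denoise(x, band)
    peaks = detect_r_peaks(x, refine=refine)
    return clean_nn(peaks)
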