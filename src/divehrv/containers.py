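"""Core signal containers shared across the pipeline.

The pipeline transforms a raw ECG trace into successively more abstract
objects: detected R-peak times, the normal-to-normal (NN) interval series,
and an evenly resampled instantaneous heart-rate signal.  Each container is
a thin dataclass around numpy arrays; all downstream feature modules accept
these types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EcgRecord", "RPeakSeries", "NNSeries", "HrSignal"]


@dataclass
class EcgRecord:
    """Single-lead ECG trace in millivolts.

    Parameters
    ----------
    samples : ndarray
        Voltage samples (mV).
    fs : float
        Sampling rate in Hz.
    subject_id, stage_id : str
        Identity of the subject-stage the trace belongs to.
    t0 : float
        Time offset (s) of the first sample relative to stage start.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    stage_id: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.fs


@dataclass
class RPeakSeries:
    """Detected R-wave peak times (s), strictly increasing.

    ``quality`` carries one flag per peak: ``auto`` (detector output),
    ``corrected`` or ``rejected`` (set during NN cleaning).
    """

    peak_times: np.ndarray
    quality: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak times must be strictly increasing")
        if self.quality is None:
            self.quality = np.array(["auto"] * len(self.peak_times), dtype=object)

    def __len__(self) -> int:
        return len(self.peak_times)


@dataclass
class NNSeries:
    """Normal-to-normal interbeat intervals.

    ``intervals`` are in milliseconds; ``interval_times`` (s) is the time of
    the beat that *ends* each interval.
    """

    intervals: np.ndarray
    interval_times: np.ndarray

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.interval_times = np.asarray(self.interval_times, dtype=float)
        if len(self.intervals) != len(self.interval_times):
            raise ValueError("intervals and interval_times length mismatch")
        if np.any(self.intervals <= 0):
            raise ValueError("NN intervals must be positive")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def beat_times(self) -> np.ndarray:
        """All beat times (s) implied by the series, including the first."""
        first = self.interval_times[0] - self.intervals[0] / 1000.0
        return np.concatenate([[first], self.interval_times])


@dataclass
class HrSignal:
    """Evenly sampled instantaneous heart rate (bpm)."""

    values: np.ndarray
    fs: float
    detrended: bool = False
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fs
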