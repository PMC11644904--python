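"""ECG conditioning, R-peak detection, Berger HR and the analysis window."""

import numpy as np
import pytest

from divehrv.containers import EcgRecord, NNSeries, RPeakSeries
from divehrv.preprocess import (
    UnanalyzableStageError,
    berger_hr,
    clean_nn,
    denoise,
    detect_r_peaks,
    ecg_to_nn,
    remove_baseline,
    to_analysis_series,
)
from divehrv.synth import RrGenParams, simulate_ecg, simulate_rr_series


def _synthetic_ecg(duration=120, seed=0, **kwargs):
    nn = simulate_rr_series(RrGenParams(duration=duration, seed=seed))
    return nn, simulate_ecg(nn, fs=100, seed=seed, **kwargs)


class TestRemoveBaseline:
    def test_constant_offset_removed(self):
        ecg = EcgRecord(samples=np.full(1000, 0.5), fs=100)
        out = remove_baseline(ecg, 0.6)
        assert abs(out.samples.mean()) < 1e-9

    def test_slow_wander_suppressed(self):
        fs = 100
        t = np.arange(0, 30, 1 / fs)
        wander = 0.5 * np.sin(2 * np.pi * 0.2 * t)
        ecg = EcgRecord(samples=wander, fs=fs)
        out = remove_baseline(ecg, 0.6)
        amp_in = np.abs(np.fft.rfft(wander))[6]  # 0.2 Hz bin of a 30 s record
        amp_out = np.abs(np.fft.rfft(out.samples))[6]
        assert amp_out < 0.2 * amp_in

    def test_spike_positions_preserved(self):
        x = np.zeros(2000)
        x[::200] = 1.0
        ecg = EcgRecord(samples=x, fs=100)
        out = remove_baseline(ecg, 0.6)
        assert np.array_equal(np.argsort(out.samples)[-10:].sort(), np.argsort(x)[-10:].sort())

    def test_window_longer_than_record_errors(self):
        with pytest.raises(ValueError):
            remove_baseline(EcgRecord(samples=np.zeros(50), fs=100), 1.0)


class TestDenoise:
    def test_out_of_band_tone_rejected(self):
        fs = 200
        t = np.arange(0, 10, 1 / fs)
        tone = np.sin(2 * np.pi * 60 * t)
        out = denoise(EcgRecord(samples=tone, fs=fs), (0.5, 40))
        core = slice(len(t) // 10, -len(t) // 10)  # steady state, no edge transients
        assert np.mean(out.samples[core] ** 2) < 0.01 * np.mean(tone[core] ** 2)

    def test_clean_ecg_nearly_unchanged(self):
        _, ecg = _synthetic_ecg(wander_amp=0.0, noise_sd=0.0)
        out = denoise(ecg)
        r = np.corrcoef(ecg.samples, out.samples)[0, 1]
        assert r >= 0.99

    def test_denoising_helps_noisy_detection(self):
        nn, ecg = _synthetic_ecg(duration=120, seed=2, wander_amp=0.0, noise_sd=0.25)
        truth = nn.beat_times

        def recall(record):
            try:
                p = detect_r_peaks(record).peak_times
            except UnanalyzableStageError:
                return 0.0
            d = np.abs(truth[:, None] - p[None, :]).min(axis=1)
            return float((d <= 0.015).mean())

        assert recall(denoise(ecg)) >= recall(ecg)

    def test_invalid_band_errors(self):
        _, ecg = _synthetic_ecg(duration=30)
        with pytest.raises(ValueError):
            denoise(ecg, (40.0, 0.5))


class TestDetectRPeaks:
    def test_noise_free_timing(self):
        nn = simulate_rr_series(
            RrGenParams(mean_rr=1000, lf_amp=0, hf_amp=0, jitter_sd=0, duration=60)
        )
        ecg = simulate_ecg(nn, fs=100, wander_amp=0, noise_sd=0)
        peaks = detect_r_peaks(ecg)
        truth = nn.beat_times
        d = np.abs(truth[:, None] - peaks.peak_times[None, :]).min(axis=1)
        assert (d <= 0.5 / 100).all()

    def test_high_sensitivity_and_ppv_at_moderate_noise(self):
        # SNR ~10 dB relative to the ~1 mV R amplitude
        nn, ecg = _synthetic_ecg(duration=300, seed=5, wander_amp=0.1, noise_sd=0.1)
        ecg = denoise(remove_baseline(ecg, 0.6))
        peaks = detect_r_peaks(ecg)
        truth = nn.beat_times
        d_truth = np.abs(truth[:, None] - peaks.peak_times[None, :]).min(axis=1)
        d_det = np.abs(peaks.peak_times[:, None] - truth[None, :]).min(axis=1)
        sensitivity = (d_truth <= 0.02).mean()
        ppv = (d_det <= 0.02).mean()
        assert sensitivity >= 0.99 and ppv >= 0.99

    def test_flatline_errors(self):
        with pytest.raises(UnanalyzableStageError):
            detect_r_peaks(EcgRecord(samples=np.zeros(1000), fs=100))


class TestCleanNn:
    def test_false_split_pair_repaired(self):
        times = np.cumsum(np.full(30, 1.0))
        times = np.sort(np.concatenate([times, [10.4]]))  # split one beat 400/600
        nn = clean_nn(RPeakSeries(peak_times=times))
        assert np.all(np.abs(nn.intervals - 1000.0) < 150.0)

    def test_clean_series_is_identity(self):
        times = np.cumsum(np.full(40, 0.8))
        nn = clean_nn(RPeakSeries(peak_times=times))
        assert np.allclose(nn.intervals, np.diff(times) * 1000)

    def test_heavy_corruption_errors(self):
        rng = np.random.default_rng(0)
        rr = np.full(50, 1.0)
        rr[rng.choice(50, 15, replace=False)] = 0.4  # 30% corrupted
        times = np.cumsum(rr)
        with pytest.raises(UnanalyzableStageError):
            clean_nn(RPeakSeries(peak_times=times))


class TestBergerHr:
    @pytest.mark.parametrize("rr_ms,bpm", [(1000, 60.0), (500, 120.0)])
    def test_exact_for_constant_rr(self, rr_ms, bpm):
        n = int(60_000 / rr_ms)
        intervals = np.full(n, float(rr_ms))
        times = np.cumsum(intervals) / 1000.0
        hr = berger_hr(NNSeries(intervals=intervals, interval_times=times))
        assert np.allclose(hr.values, bpm, atol=1e-9)

    def test_beat_count_conserved(self):
        nn = simulate_rr_series(RrGenParams(duration=300, seed=8))
        hr = berger_hr(nn)
        beats_est = np.sum(hr.values / 60.0) / hr.fs
        n_in_window = np.sum(
            (nn.beat_times >= hr.t0 - 1 / hr.fs) & (nn.beat_times <= hr.times[-1] + 1 / hr.fs)
        )
        assert abs(beats_est - n_in_window) <= 2

    def test_modulation_frequency_preserved(self):
        p = RrGenParams(lf_amp=50, hf_amp=0, jitter_sd=0, duration=600, seed=0)
        hr = berger_hr(simulate_rr_series(p))
        x = hr.values - hr.values.mean()
        freqs = np.fft.rfftfreq(len(x), 1 / hr.fs)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(x)))]
        assert abs(peak - p.lf_freq) <= freqs[1]


class TestAnalysisSeries:
    def test_standard_stage_gives_210_samples(self):
        intervals = np.full(310, 1000.0)
        nn = NNSeries(intervals=intervals, interval_times=np.cumsum(intervals) / 1000)
        hr1 = to_analysis_series(berger_hr(nn), washin_s=90, stage_len_s=300)
        assert abs(len(hr1) - 210) <= 1
        assert hr1.fs == 1.0

    def test_constant_input_detrends_to_zero(self):
        intervals = np.full(310, 1000.0)
        nn = NNSeries(intervals=intervals, interval_times=np.cumsum(intervals) / 1000)
        hr1 = to_analysis_series(berger_hr(nn), 90, 300)
        assert np.abs(hr1.values).max() < 1e-6
        assert abs(hr1.values.mean()) < 1e-6

    def test_empty_window_errors(self):
        intervals = np.full(310, 1000.0)
        nn = NNSeries(intervals=intervals, interval_times=np.cumsum(intervals) / 1000)
        with pytest.raises(ValueError):
            to_analysis_series(berger_hr(nn), washin_s=300, stage_len_s=300)


class TestPipelineComposition:
    def test_nn_recovery_on_clean_synthetic(self):
        nn, ecg = _synthetic_ecg(duration=300, seed=1, wander_amp=0.1, noise_sd=0.01)
        out = ecg_to_nn(ecg)
        # compare interval series where beat times align
        truth_times = nn.interval_times
        d = np.abs(truth_times[:, None] - out.interval_times[None, :])
        j = d.argmin(axis=1)
        ok = d.min(axis=1) <= 0.02
        err = np.abs(out.intervals[j[ok]] - nn.intervals[ok])
        assert (err <= 10.0).mean() >= 0.99  # within one 100 Hz sample period
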