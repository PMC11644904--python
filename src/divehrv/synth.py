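"""Synthetic dive-cohort generator.

Emulates the data layout of a hyperbaric cognitive-performance study: a
pooled exposure design (16 gas x exercise groups), per-stage RR-interval
series with controllable low-frequency (LF, 0.04-0.15 Hz) and
high-frequency (HF, 0.15-0.4 Hz) autonomic modulation, stylized 100 Hz ECG
traces built from those RR series, and MATB-style subtask scores whose
expected fractional decrement is a linear function of the exposure
covariates (exercise, high N2, high CO2, high O2).

The generator is the ground-truth oracle for every downstream module: the
injected modulation amplitudes validate the spectral estimators, the beat
times validate the R-peak detector, and the decrement betas validate the
association machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EcgRecord, NNSeries

__all__ = [
    "StageRecord",
    "ExposureDesign",
    "RrGenParams",
    "MatbGenParams",
    "Cohort",
    "GROUP_TEMPLATES",
    "SUBTASKS",
    "make_exposure_design",
    "simulate_rr_series",
    "simulate_ecg",
    "simulate_matb_scores",
    "stage_rr_params",
    "simulate_cohort",
    "write_cohort",
]

KPA_PER_ATA = 101.325

SUBTASKS = ("tracking", "monitor", "communication", "pump")

# Pooled exposure groups: (label, exercise, [(ata, fico2, fio2), ...]).
# FiN2 is the balance gas (1 - FiCO2 - FiO2).  Groups exposed to elevated
# nitrogen pool two chamber pressures (4.7 and 5.8 ATA); the variant used
# for a given subject alternates deterministically with the seed.
GROUP_TEMPLATES = [
    ("01_air", 0, [(1.0, 0.0, 0.21)]),
    ("02_CO2", 0, [(1.0, 0.075, 0.21)]),
    ("03_O2", 0, [(1.0, 0.0, 1.0)]),
    ("04_CO2O2", 0, [(1.0, 0.075, 0.925)]),
    ("05_N2", 0, [(4.7, 0.0, 0.045), (5.8, 0.0, 0.036)]),
    ("06_N2O2", 0, [(5.8, 0.0, 0.21)]),
    ("07_CO2N2", 0, [(4.7, 0.016, 0.045), (5.8, 0.013, 0.036)]),
    ("08_CO2N2O2", 0, [(5.8, 0.013, 0.21)]),
    ("09_ex_air", 1, [(1.0, 0.0, 0.21)]),
    ("10_ex_CO2", 1, [(1.0, 0.075, 0.21)]),
    ("11_ex_O2", 1, [(1.0, 0.0, 1.0)]),
    ("12_ex_CO2O2", 1, [(1.0, 0.075, 0.925)]),
    ("13_ex_N2", 1, [(4.7, 0.0, 0.045), (5.8, 0.0, 0.036)]),
    ("14_ex_N2O2", 1, [(5.8, 0.0, 0.21)]),
    ("15_ex_CO2N2", 1, [(4.7, 0.016, 0.045), (5.8, 0.013, 0.036)]),
    ("16_ex_CO2N2O2", 1, [(5.8, 0.013, 0.21)]),
]

BASELINE_GROUP = "01_air"


@dataclass
class StageRecord:
    """One subject-stage exposure: gas fractions, partial pressures, flags.

    Partial pressures are FiX * ATA rounded to 2 decimals; the binary
    covariates follow the pooled-group definitions: high_co2 when any CO2
    is inspired, high_n2 when PiN2 exceeds 1 ATA, high_o2 when PiO2
    exceeds 0.5 ATA.
    """

    subject_id: str
    stage_id: str
    group_label: str
    ata: float
    fico2: float
    fin2: float
    fio2: float
    exercise: int
    stage_order: int
    pico2: float = field(init=False)
    pin2: float = field(init=False)
    pio2: float = field(init=False)
    kpa: float = field(init=False)
    high_n2: int = field(init=False)
    high_co2: int = field(init=False)
    high_o2: int = field(init=False)

    def __post_init__(self) -> None:
        frac_sum = self.fico2 + self.fin2 + self.fio2
        if abs(frac_sum - 1.0) > 1e-3:
            raise ValueError(f"gas fractions sum to {frac_sum}, not 1")
        self.pico2 = round(self.fico2 * self.ata, 2)
        self.pin2 = round(self.fin2 * self.ata, 2)
        self.pio2 = round(self.fio2 * self.ata, 2)
        self.kpa = round(self.ata * KPA_PER_ATA, 1)
        self.high_co2 = int(self.fico2 > 0)
        self.high_n2 = int(self.pin2 > 1.0)
        self.high_o2 = int(self.pio2 > 0.5)


@dataclass
class ExposureDesign:
    """All stage records of a cohort plus the group templates used."""

    records: list
    n_subjects: int
    stages_per_subject: int = 16

    @property
    def groups(self):
        return GROUP_TEMPLATES

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])


def make_exposure_design(n_subjects: int, seed: int = 0) -> ExposureDesign:
    """Instantiate the 16 pooled exposure groups once per subject.

    High-N2 groups carry one of the two pooled chamber pressures; the
    variant alternates across subjects, with the starting parity set by
    the seed.  Stage order within a subject is a seeded permutation.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        order = rng.permutation(len(GROUP_TEMPLATES)) + 1
        for g, (label, exercise, variants) in enumerate(GROUP_TEMPLATES):
            ata, fico2, fio2 = variants[(i + seed) % len(variants)]
            fin2 = round(1.0 - fico2 - fio2, 6)
            records.append(
                StageRecord(
                    subject_id=sid,
                    stage_id=f"{sid}_{label}",
                    group_label=label,
                    ata=ata,
                    fico2=fico2,
                    fin2=fin2,
                    fio2=fio2,
                    exercise=exercise,
                    stage_order=int(order[g]),
                )
            )
    return ExposureDesign(records=records, n_subjects=n_subjects)


@dataclass
class RrGenParams:
    """Parameters of the additive-sinusoid RR generator.

    RR(t) = mean_rr + lf_amp*sin(2*pi*lf_freq*t) + hf_amp*sin(2*pi*hf_freq*t)
    + white jitter.  The two sinusoids place controllable power in the LF
    and HF bands; band power scales with amplitude squared.
    """

    mean_rr: float = 900.0  # ms
    lf_amp: float = 35.0  # ms
    hf_amp: float = 30.0  # ms
    lf_freq: float = 0.1  # Hz
    hf_freq: float = 0.25  # Hz
    jitter_sd: float = 10.0  # ms
    duration: float = 300.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if not 400.0 <= self.mean_rr <= 1500.0:
            raise ValueError("mean_rr must lie in [400, 1500] ms")
        if not 0.04 <= self.lf_freq <= 0.15:
            raise ValueError("lf_freq must lie in the LF band (0.04-0.15 Hz)")
        if not 0.15 <= self.hf_freq <= 0.4:
            raise ValueError("hf_freq must lie in the HF band (0.15-0.4 Hz)")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def simulate_rr_series(params: RrGenParams) -> NNSeries:
    """Generate an RR series with sinusoidal LF/HF modulation plus jitter."""
    rng = np.random.default_rng(params.seed)
    times = [0.0]
    intervals = []
    t = 0.0
    while t < params.duration:
        rr = (
            params.mean_rr
            + params.lf_amp * np.sin(2 * np.pi * params.lf_freq * t)
            + params.hf_amp * np.sin(2 * np.pi * params.hf_freq * t)
        )
        if params.jitter_sd > 0:
            rr += rng.normal(0.0, params.jitter_sd)
        rr = max(rr, 200.0)  # guard against non-physiologic collapse
        t += rr / 1000.0
        times.append(t)
        intervals.append(rr)
    if len(times) < 3:
        raise ValueError("duration too short to contain >= 3 beats")
    return NNSeries(
        intervals=np.array(intervals), interval_times=np.array(times[1:])
    )


def _beat_template(fs: float) -> tuple[np.ndarray, int]:
    """Stylized beat: dominant R spike with small Q and S deflections.

    Widths give a ~100 ms QRS complex whose energy sits below ~35 Hz, so
    the standard 0.5-40 Hz conditioning band passes it essentially intact.
    """
    half = int(round(0.08 * fs))
    t = (np.arange(-half, half + 1)) / fs
    r = 1.0 * np.exp(-0.5 * (t / 0.016) ** 2)
    q = -0.12 * np.exp(-0.5 * ((t + 0.036) / 0.011) ** 2)
    s = -0.18 * np.exp(-0.5 * ((t - 0.036) / 0.013) ** 2)
    return r + q + s, half


def simulate_ecg(
    nn: NNSeries,
    fs: float = 100.0,
    wander_amp: float = 0.1,
    wander_freq: float = 0.25,
    noise_sd: float = 0.01,
    seed: int = 0,
    subject_id: str = "",
    stage_id: str = "",
) -> EcgRecord:
    """Render an ECG trace with one template beat per RR beat time.

    Baseline wander is a sub-0.5 Hz sinusoid; measurement noise is white.
    True R-peak times equal ``nn.beat_times`` (recoverable within one
    sample period by construction).
    """
    if fs < 50:
        raise ValueError("fs must be >= 50 Hz")
    if wander_freq >= 0.5:
        raise ValueError("baseline wander must stay below 0.5 Hz")
    rng = np.random.default_rng(seed)
    beats = nn.beat_times
    lead_in = 0.5  # pre-roll so the first beat is fully rendered
    t0 = -lead_in
    n = int(np.ceil((beats[-1] + lead_in + 0.4) * fs))
    x = np.zeros(n)
    template, half = _beat_template(fs)
    for bt in beats:
        c = int(round((bt - t0) * fs))
        lo, hi = c - half, c + half + 1
        tlo = max(0, -lo)
        thi = len(template) - max(0, hi - n)
        x[max(lo, 0) : min(hi, n)] += template[tlo:thi]
    t = t0 + np.arange(n) / fs
    if wander_amp > 0:
        x += wander_amp * np.sin(2 * np.pi * wander_freq * t + rng.uniform(0, 2 * np.pi))
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=n)
    return EcgRecord(
        samples=x, fs=fs, subject_id=subject_id, stage_id=stage_id, t0=t0
    )


@dataclass
class MatbGenParams:
    """Effect structure of the MATB subtask-score generator.

    Betas are additive effects of the exposure covariates on the expected
    fractional performance decrement (0 = no decrement).  Defaults are set
    so the resulting stage-impairment-score distributions mirror the
    pattern the analysis assumes: resting stages mostly 0 or mildly
    impaired, exercising stages spread across 1-4.
    """

    baseline_mean: float = 100.0
    baseline_sd: float = 10.0
    beta_exercise: float = 0.12
    beta_n2: float = 0.10
    beta_co2: float = 0.08
    beta_o2: float = 0.03
    noise_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        for name in ("beta_exercise", "beta_n2", "beta_co2", "beta_o2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 (decrement direction)")


def simulate_matb_scores(
    design: ExposureDesign, params: MatbGenParams
) -> pd.DataFrame:
    """Generate 4 subtask scores per stage (higher = better performance).

    Expected fractional decrement per stage is the linear combination of
    betas and exposure covariates, applied multiplicatively to the
    subject's per-subtask baseline with multiplicative Gaussian noise.
    The air-rest stage has zero expected decrement.
    """
    if not design.records:
        raise ValueError("design is empty")
    rng = np.random.default_rng(params.seed)
    baselines = {}
    rows = []
    for rec in design.records:
        if rec.subject_id not in baselines:
            baselines[rec.subject_id] = params.baseline_mean + rng.normal(
                0.0, params.baseline_sd, size=len(SUBTASKS)
            )
        base = baselines[rec.subject_id]
        d = (
            params.beta_exercise * rec.exercise
            + params.beta_n2 * rec.high_n2
            + params.beta_co2 * rec.high_co2
            + params.beta_o2 * rec.high_o2
        )
        d = min(d, 0.95)
        noise = (
            rng.normal(0.0, params.noise_sd, size=len(SUBTASKS))
            if params.noise_sd > 0
            else np.zeros(len(SUBTASKS))
        )
        scores = base * (1.0 - d) * (1.0 + noise)
        row = {
            "subject_id": rec.subject_id,
            "stage_id": rec.stage_id,
            "group_label": rec.group_label,
            "decrement_true": d,
        }
        for k, name in enumerate(SUBTASKS):
            row[name] = scores[k]
            row[f"baseline_{name}"] = base[k]
        rows.append(row)
    return pd.DataFrame(rows)


def stage_rr_params(
    record: StageRecord,
    duration: float = 300.0,
    subject_shift: float = 0.0,
    seed: int = 0,
) -> RrGenParams:
    """Map exposure covariates to autonomic RR-generator parameters.

    Exercise shortens mean RR and withdraws vagal (HF) modulation;
    hypercapnia and hyperoxia raise HF modulation; elevated N2 mildly
    damps both bands.  These directions give the synthetic cohort an
    HRV-exposure coupling for the association and ML modules to detect.
    """
    mean_rr = 900.0 + subject_shift
    lf, hf = 35.0, 30.0
    if record.exercise:
        mean_rr -= 250.0
        lf *= 0.6
        hf *= 0.35
    if record.high_co2:
        mean_rr -= 40.0
        hf *= 1.25
    if record.high_o2:
        mean_rr += 40.0
        hf *= 1.15
    if record.high_n2:
        lf *= 0.9
        hf *= 0.8
    mean_rr = float(np.clip(mean_rr, 420.0, 1480.0))
    return RrGenParams(
        mean_rr=mean_rr,
        lf_amp=lf,
        hf_amp=hf,
        jitter_sd=10.0,
        duration=duration,
        seed=seed,
    )


def simulate_score_frame(
    n_subjects: int = 37,
    betas: tuple[float, float, float, float] = (0.33, 0.72, 0.56, 0.21),
    sd_subject: float = 0.3,
    sd_noise: float = 0.6,
    seed: int = 0,
    feature_effect: float = 0.0,
) -> pd.DataFrame:
    """Design table with a continuous score linear in the exposure covariates.

    Used to calibrate the repeated-measures machinery: the score is
    beta_exercise*exercise + beta_n2*high_n2 + beta_co2*high_co2 +
    beta_o2*high_o2 plus a subject random intercept and residual noise,
    together with an independent standard-normal ``feature`` column
    (optionally carrying its own effect).  Under feature_effect = 0 the
    feature coefficient is exactly null.
    """
    rng = np.random.default_rng(seed)
    design = make_exposure_design(n_subjects, seed=seed)
    df = design.to_frame()
    intercepts = {
        s: rng.normal(0.0, sd_subject) for s in df["subject_id"].unique()
    }
    df["feature"] = rng.normal(0.0, 1.0, size=len(df))
    df["score"] = (
        betas[0] * df["exercise"]
        + betas[1] * df["high_n2"]
        + betas[2] * df["high_co2"]
        + betas[3] * df["high_o2"]
        + df["subject_id"].map(intercepts)
        + feature_effect * df["feature"]
        + rng.normal(0.0, sd_noise, size=len(df))
    )
    return df


@dataclass
class Cohort:
    """A fully simulated cohort: design table, RR series, MATB scores."""

    stages: pd.DataFrame
    nn: dict
    matb: pd.DataFrame
    truth: dict


def simulate_cohort(
    n_subjects: int = 37,
    seed: int = 0,
    dropout: float = 0.0,
    stage_len_s: float = 300.0,
    matb_params: MatbGenParams | None = None,
) -> Cohort:
    """Simulate a complete cohort at the RR-series level.

    One RR series and one MATB score row per subject-stage.  ``dropout``
    randomly removes non-baseline stages to emulate attrition; the
    air-rest baseline stage is always retained.
    """
    rng = np.random.default_rng(seed)
    design = make_exposure_design(n_subjects, seed=seed)
    if matb_params is None:
        matb_params = MatbGenParams(seed=int(rng.integers(2**31)))
    matb = simulate_matb_scores(design, matb_params)
    subject_shift = {}
    nn = {}
    truth = {"rr_params": {}, "matb_params": asdict(matb_params)}
    kept = []
    for rec in design.records:
        if rec.subject_id not in subject_shift:
            subject_shift[rec.subject_id] = rng.normal(0.0, 60.0)
        if (
            dropout > 0
            and rec.group_label != BASELINE_GROUP
            and rng.uniform() < dropout
        ):
            continue
        params = stage_rr_params(
            rec,
            duration=stage_len_s,
            subject_shift=subject_shift[rec.subject_id],
            seed=int(rng.integers(2**31)),
        )
        nn[rec.stage_id] = simulate_rr_series(params)
        truth["rr_params"][rec.stage_id] = asdict(params)
        kept.append(rec)
    stages = pd.DataFrame([asdict(r) for r in kept])
    matb = matb[matb["stage_id"].isin(stages["stage_id"])].reset_index(drop=True)
    return Cohort(stages=stages, nn=nn, matb=matb, truth=truth)


def write_cohort(
    cohort: Cohort, outdir: str | Path, fs: float = 100.0, seed: int = 0
) -> None:
    """Write a cohort directory: per-stage ECG CSVs plus design tables."""
    outdir = Path(outdir)
    (outdir / "ecg").mkdir(parents=True, exist_ok=True)
    cohort.stages.to_csv(outdir / "stages.csv", index=False)
    cohort.matb.to_csv(outdir / "matb.csv", index=False)
    rng = np.random.default_rng(seed)
    for stage_id, nn in cohort.nn.items():
        ecg = simulate_ecg(nn, fs=fs, seed=int(rng.integers(2**31)), stage_id=stage_id)
        df = pd.DataFrame({"time_s": ecg.times, "mv": ecg.samples})
        df.to_csv(outdir / "ecg" / f"{stage_id}.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
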