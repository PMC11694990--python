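"""Synthetic cardiotocography cohorts.

Generates paired fetal (FHR) and maternal (MHR) heart-rate recordings with the
statistical structure the downstream compression analysis assumes: a slow
baseline trend (sinusoid mixture with periods of minutes), fast AR(1)
fluctuations, transient acceleration/deceleration events in the fetal channel,
a lagged maternal-to-fetal coupling term, and short sample-loss gaps in the
maternal channel.  Acidemia is emulated as reduced fetal fast-fluctuation
variance together with strengthened maternal-to-fetal coupling, both scaled by
a single dimensionless ``effect_size`` knob (0 makes the two groups
exchangeable).

This is a statistical emulator, not a mechanistic cardiovascular model: it
exists so the pipeline can be exercised and validated end to end on data whose
ground truth is known.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

ACIDEMIC = "acidemic"
NONACIDEMIC = "nonacidemic"
PH_CUTOFF = 7.15

#: pH sampling ranges per group; consistent with the 7.15 cutoff and the
#: observed cord-blood pH range of term deliveries (min ~7.05, max ~7.37).
PH_RANGE = {ACIDEMIC: (7.00, 7.14), NONACIDEMIC: (7.16, 7.37)}


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for one synthetic cohort.

    Defaults reproduce the emulated study: 54 non-acidemic and 7 acidemic
    subjects at 4 Hz, recording durations centred on 119.3 min with ~1 min
    jitter, and a maternal sample-loss fraction of 1e-4 (0.01%).
    """

    n_nonacidemic: int = 54
    n_acidemic: int = 7
    fs: float = 4.0
    duration_min: float = 119.3
    jitter_min: float = 1.0
    effect_size: float = 0.0
    coupling_strength: dict = field(
        default_factory=lambda: {ACIDEMIC: 0.10, NONACIDEMIC: 0.10}
    )
    maternal_loss_fraction: float = 1e-4
    fhr_baseline: float = 140.0
    mhr_baseline: float = 80.0
    fhr_noise_sd: float = 3.0
    mhr_noise_sd: float = 2.0
    ar_coeff: float = 0.95
    fhr_band: tuple = (60.0, 200.0)
    mhr_band: tuple = (40.0, 150.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_nonacidemic < 0 or self.n_acidemic < 0:
            raise ValueError("group sizes must be non-negative")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError("fs must be a positive finite sampling rate")
        if not np.isfinite(self.duration_min) or self.duration_min <= 0:
            raise ValueError("duration_min must be positive and finite")
        if not 0.0 <= self.maternal_loss_fraction < 1.0:
            raise ValueError("maternal_loss_fraction must lie in [0, 1)")
        for v in (self.jitter_min, self.effect_size, self.fhr_noise_sd,
                  self.mhr_noise_sd, self.ar_coeff):
            if not np.isfinite(v):
                raise ValueError("configuration values must be finite")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


@dataclass
class SubjectRecord:
    """One subject's paired heart-rate recording with outcome label."""

    subject_id: str
    fhr: np.ndarray
    mhr: np.ndarray
    ph: float
    group: str
    origin: str = "original"
    fs: float = 4.0

    def __post_init__(self):
        expected = ACIDEMIC if self.ph < PH_CUTOFF else NONACIDEMIC
        if self.group != expected:
            raise ValueError(
                f"group {self.group!r} inconsistent with pH {self.ph} "
                f"(cutoff {PH_CUTOFF})"
            )


def _slow_trend(n: int, fs: float, amplitudes, rng: np.random.Generator) -> np.ndarray:
    """Sinusoid mixture with periods >= 2 min (slow, sub-Nyquist-of-trend)."""
    t = np.arange(n) / fs
    out = np.zeros(n)
    for amp in amplitudes:
        period_s = rng.uniform(120.0, 1200.0)
        phase = rng.uniform(0.0, 2 * np.pi)
        out += amp * np.sin(2 * np.pi * t / period_s + phase)
    return out


def _ar1(n: int, sd: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = rng.normal(0.0, innov_sd, size=n)
    x = lfilter([1.0], [1.0, -phi], eps)
    return np.asarray(x)


def _event_bumps(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian-shaped accelerations/decelerations, 15-60 s wide."""
    out = np.zeros(n)
    duration_min = n / fs / 60.0
    n_events = rng.poisson(duration_min / 10.0)  # ~1 event per 10 min
    t = np.arange(n)
    for _ in range(n_events):
        center = rng.uniform(0, n)
        width_s = rng.uniform(15.0, 60.0)
        sigma = width_s * fs / 4.0  # bump visually spans ~4 sigma
        amp = rng.uniform(10.0, 25.0) * rng.choice([-1.0, 1.0])
        out += amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return out


def generate_subject(
    config: CohortConfig, group: str, rng: np.random.Generator,
    subject_id: str = "s000",
) -> SubjectRecord:
    """Draw one subject's paired FHR/MHR recording.

    The maternal channel is generated first; the fetal channel receives a
    lagged (2 s), mean-centred copy of it scaled by the group's coupling
    strength.  In the acidemic group the fetal fast-noise standard deviation
    is divided by ``1 + effect_size`` and the coupling multiplied by the same
    factor, so ``effect_size = 0`` makes the groups exchangeable.
    """
    config.validate()
    if group not in (ACIDEMIC, NONACIDEMIC):
        raise ValueError(f"unknown group label {group!r}")

    fs = config.fs
    dur = config.duration_min + rng.uniform(-config.jitter_min, config.jitter_min)
    n = int(round(dur * 60.0 * fs))

    mhr = (
        config.mhr_baseline
        + _slow_trend(n, fs, (4.0, 2.0, 1.0), rng)
        + _ar1(n, config.mhr_noise_sd, config.ar_coeff, rng)
    )
    np.clip(mhr, *config.mhr_band, out=mhr)

    coupling = config.coupling_strength[group]
    fhr_sd = config.fhr_noise_sd
    if group == ACIDEMIC:
        fhr_sd = fhr_sd / (1.0 + config.effect_size)
        coupling = coupling * (1.0 + config.effect_size)

    lag = int(round(2.0 * fs))  # maternal influence arrives with ~2 s delay
    mhr_centered = mhr - mhr.mean()
    mhr_lagged = np.concatenate([np.zeros(lag), mhr_centered[: n - lag]])

    fhr = (
        config.fhr_baseline
        + _slow_trend(n, fs, (5.0, 3.0, 2.0), rng)
        + _ar1(n, fhr_sd, config.ar_coeff, rng)
        + _event_bumps(n, fs, rng)
        + coupling * mhr_lagged
    )
    np.clip(fhr, *config.fhr_band, out=fhr)

    lo, hi = PH_RANGE[group]
    ph = float(rng.uniform(lo, hi))
    return SubjectRecord(subject_id=subject_id, fhr=fhr, mhr=mhr, ph=ph,
                         group=group, origin="original", fs=fs)


def inject_missing(
    series: np.ndarray, loss_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Mark contiguous short runs of samples as missing (NaN).

    The total number of missing samples is ``round(len(series) *
    loss_fraction)``, placed as non-overlapping runs of 1-4 samples at random
    positions; gap positions are reproducible under a fixed generator state.
    """
    if not 0.0 <= loss_fraction < 1.0:
        raise ValueError("loss_fraction must lie in [0, 1)")
    out = np.array(series, dtype=float, copy=True)
    n = out.size
    target = int(round(n * loss_fraction))
    if target == 0:
        return out
    missing = np.zeros(n, dtype=bool)
    placed = 0
    attempts = 0
    while placed < target and attempts < 100 * target:
        attempts += 1
        run = int(min(rng.integers(1, 5), target - placed))
        start = int(rng.integers(0, n - run + 1))
        if missing[start : start + run].any():
            continue
        missing[start : start + run] = True
        placed += run
    out[missing] = np.nan
    return out


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Generate the full cohort; bit-reproducible under ``config.seed``.

    Maternal-channel losses are injected here (the fetal channel is loss-free,
    as in the emulated study).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    n_total = config.n_nonacidemic + config.n_acidemic
    children = ss.spawn(n_total)
    groups = [NONACIDEMIC] * config.n_nonacidemic + [ACIDEMIC] * config.n_acidemic
    subjects = []
    for i, (grp, child) in enumerate(zip(groups, children)):
        rng = np.random.default_rng(child)
        rec = generate_subject(config, grp, rng, subject_id=f"s{i:03d}")
        rec.mhr = inject_missing(rec.mhr, config.maternal_loss_fraction, rng)
        subjects.append(rec)
    return subjects


# ---------------------------------------------------------------------------
# Cohort persistence: one CSV per subject plus a manifest CSV.

def write_cohort(subjects: list[SubjectRecord], out_dir, seed=None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "ph", "group", "duration_min", "fs", "origin", "seed"])
        for rec in subjects:
            w.writerow([
                rec.subject_id, f"{rec.ph:.4f}", rec.group,
                f"{len(rec.fhr) / rec.fs / 60.0:.4f}", rec.fs, rec.origin,
                "" if seed is None else seed,
            ])
            path = out_dir / f"{rec.subject_id}.csv"
            with open(path, "w", newline="") as sf:
                sw = csv.writer(sf)
                sw.writerow(["time_s", "fhr_bpm", "mhr_bpm"])
                t = np.arange(len(rec.fhr)) / rec.fs
                for ti, f, m in zip(t, rec.fhr, rec.mhr):
                    sw.writerow([
                        f"{ti:.2f}",
                        "" if np.isnan(f) else f"{f:.3f}",
                        "" if np.isnan(m) else f"{m:.3f}",
                    ])
    return manifest


def read_cohort(cohort_dir) -> list[SubjectRecord]:
    cohort_dir = Path(cohort_dir)
    manifest = cohort_dir / "manifest.csv"
    subjects = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            data = np.genfromtxt(
                cohort_dir / f"{row['subject_id']}.csv",
                delimiter=",", skip_header=1, usecols=(1, 2),
                missing_values="", filling_values=np.nan,
            )
            subjects.append(SubjectRecord(
                subject_id=row["subject_id"],
                fhr=data[:, 0], mhr=data[:, 1],
                ph=float(row["ph"]), group=row["group"],
                origin=row["origin"], fs=float(row["fs"]),
            ))
    return subjects
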