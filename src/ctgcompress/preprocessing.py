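"""Signal cleaning, trend/residual decomposition and 10-minute segmentation.

The cleaning stage applies the cardiotocography artifact rules (values below
60 bpm, above 200 bpm, or jumping by more than 25 bpm from the previous valid
sample are invalid), fills short invalid runs (<= 2 s) by linear interpolation
and longer runs by replicating the preceding valid stretch of equal length.
The maternal channel is first shifted by +50 bpm so both channels share the
fetal artifact thresholds.

The trend is a centered moving average over 17 samples (2 s of look-ahead at
4 Hz); the residual is the pointwise difference between signal and trend on
the trend's support.  Each component is cut into consecutive 10-minute
segments anchored at the recording end, labelled h1-a..h1-f, h2-a..h2-f, so
h2-f is always the last 10 minutes before the recording stops; a leading
partial segment is kept only if it is strictly longer than 5 minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Canonical segment labels: first hour slots a-f, then second hour slots a-f.
SEGMENT_LABELS = [f"{h}-{s}" for h in ("h1", "h2") for s in "abcdef"]

MHR_SHIFT_BPM = 50.0


@dataclass(frozen=True)
class TrendConfig:
    """Centered moving-average settings (window must be odd)."""

    window_samples: int = 17
    fs: float = 4.0

    def __post_init__(self):
        if self.window_samples < 3 or self.window_samples % 2 == 0:
            raise ValueError("window_samples must be odd and >= 3")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def half_window(self) -> int:
        return (self.window_samples - 1) // 2

    @property
    def delay_seconds(self) -> float:
        """Real-time delay implied by the look-ahead half of the window."""
        return self.half_window / self.fs


@dataclass
class SignalSegment:
    """A labelled nominal 10-minute window of one channel component."""

    subject_id: str
    channel: str  # fetal | maternal
    component: str  # raw | trend | residual
    label: str  # e.g. "h2-f"
    samples: np.ndarray
    fs: float

    @property
    def hour(self) -> str:
        return self.label.split("-")[0]

    @property
    def slot(self) -> str:
        return self.label.split("-")[1]


def _find_runs(mask: np.ndarray):
    """Start/stop (half-open) index pairs of True runs in a boolean mask."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return list(zip(idx[0::2], idx[1::2]))


def _invalid_mask(x, low, high, max_step):
    """Range/gap rules vectorised; the step rule relative to the previous
    valid sample needs a scan, so it is only run when a coarse check fires."""
    invalid = ~np.isfinite(x) | (x < low) | (x > high)
    coarse_step = np.zeros_like(invalid)
    with np.errstate(invalid="ignore"):
        coarse_step[1:] = np.abs(np.diff(x)) > max_step
    if coarse_step.any():
        last_valid = None
        for i in range(x.size):
            if invalid[i]:
                continue
            if last_valid is not None and abs(x[i] - last_valid) > max_step:
                invalid[i] = True
            else:
                last_valid = x[i]
    return invalid


def _fill_invalid(x, invalid, fs):
    """Fill invalid runs: interpolate short ones, replicate for long ones."""
    out = x.copy()
    max_interp = int(round(2.0 * fs))  # "loss periods do not exceed 2 seconds"
    for start, stop in _find_runs(invalid):
        run = stop - start
        if run <= max_interp and start > 0 and stop < out.size:
            left, right = out[start - 1], out[stop]
            out[start:stop] = np.interp(
                np.arange(1, run + 1), [0, run + 1], [left, right]
            )
            continue
        # replicate the previous valid stretch of equal length
        if start - run >= 0 and not invalid[start - run : start].any():
            out[start:stop] = out[start - run : start]
        elif stop + run <= out.size and not invalid[stop : stop + run].any():
            out[start:stop] = out[stop : stop + run]
        else:  # degenerate: nearest valid value
            valid_idx = np.flatnonzero(~invalid)
            nearest = valid_idx[np.argmin(np.abs(valid_idx - start))]
            out[start:stop] = out[nearest]
    return out


def clean_heart_rate(series, fs, low=60.0, high=200.0, max_step=25.0,
                     max_passes=5):
    """Remove artifacts from a heart-rate series.

    Rules are applied iteratively (a replacement can create a new >25 bpm step
    at its boundary) up to ``max_passes``; any samples still invalid after
    that are filled with the nearest valid value so the output is always
    fully defined.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("series must have at least 2 samples")
    x = x.copy()
    for _ in range(max_passes):
        invalid = _invalid_mask(x, low, high, max_step)
        if not invalid.any():
            return x
        if invalid.all():
            raise ValueError("series has no valid samples")
        x = _fill_invalid(x, invalid, fs)
    invalid = _invalid_mask(x, low, high, max_step)
    if invalid.any():
        valid_idx = np.flatnonzero(~invalid)
        for start, stop in _find_runs(invalid):
            nearest = valid_idx[np.argmin(np.abs(valid_idx - start))]
            x[start:stop] = x[nearest]
    return x


def shift_mhr(series):
    """Scale conversion of the maternal channel: add 50 bpm to every sample."""
    return np.asarray(series, dtype=float) + MHR_SHIFT_BPM


def fraction_lost(series) -> float:
    """Missing samples (NaN gap markers) over total samples."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    return float(np.isnan(x).sum() / x.size)


def align_pair(fhr, mhr):
    """Truncate both channels' tails to the shorter duration."""
    fhr = np.asarray(fhr, dtype=float)
    mhr = np.asarray(mhr, dtype=float)
    if fhr.size == 0 or mhr.size == 0:
        raise ValueError("cannot align an empty series")
    n = min(fhr.size, mhr.size)
    return fhr[:n], mhr[:n]


def moving_average_trend(series, cfg: TrendConfig):
    """Centered moving average; support shrinks by half a window per side."""
    x = np.asarray(series, dtype=float)
    if x.size < cfg.window_samples:
        raise ValueError("series shorter than the smoothing window")
    kernel = np.full(cfg.window_samples, 1.0 / cfg.window_samples)
    return np.convolve(x, kernel, mode="valid")


def decompose(series, cfg: TrendConfig):
    """Split into (trend, residual); trend + residual == series on support."""
    x = np.asarray(series, dtype=float)
    trend = moving_average_trend(x, cfg)
    h = cfg.half_window
    residual = x[h : x.size - h] - trend
    return trend, residual


def segment(series, fs, subject_id="", channel="", component="raw",
            seg_minutes=10.0, min_minutes=5.0):
    """Cut a series into labelled consecutive 10-minute windows.

    Windows are anchored to the recording END (the last window is h2-f); a
    leading partial window is kept only if strictly longer than
    ``min_minutes``.  Returns ``(segments, n_discarded)``.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    seg_len = int(round(seg_minutes * 60.0 * fs))
    min_len = int(round(min_minutes * 60.0 * fs))
    n_full = x.size // seg_len
    rem = x.size - n_full * seg_len

    segments, discarded = [], 0
    pieces = []
    if rem > 0:
        pieces.append((0, rem, True))
    for j in range(n_full):
        start = rem + j * seg_len
        pieces.append((start, start + seg_len, False))

    n_pieces = len(pieces)
    for idx, (start, stop, partial) in enumerate(pieces):
        label_idx = len(SEGMENT_LABELS) - n_pieces + idx
        if label_idx < 0 or (partial and (stop - start) <= min_len):
            discarded += 1
            continue
        segments.append(SignalSegment(
            subject_id=subject_id, channel=channel, component=component,
            label=SEGMENT_LABELS[label_idx], samples=x[start:stop], fs=fs,
        ))
    return segments, discarded


def preprocess_subject(record, trend_cfg: TrendConfig | None = None):
    """Full per-subject pipeline: shift (MHR) -> clean -> align -> decompose
    -> segment, for both channels and both components.

    Returns a dict with the segmented components, per-channel loss fractions
    and the discarded-segment count, e.g.::

        out["segments"][("fetal", "residual")] -> list[SignalSegment]
    """
    cfg = trend_cfg or TrendConfig(fs=record.fs)
    fs = record.fs
    losses = {
        "fetal": fraction_lost(record.fhr),
        "maternal": fraction_lost(record.mhr),
    }
    fhr = clean_heart_rate(record.fhr, fs)
    mhr = clean_heart_rate(shift_mhr(record.mhr), fs)
    fhr, mhr = align_pair(fhr, mhr)

    out = {"losses": losses, "segments": {}, "discarded": 0, "series": {}}
    for channel, series in (("fetal", fhr), ("maternal", mhr)):
        trend, residual = decompose(series, cfg)
        for component, comp_series in (("trend", trend), ("residual", residual)):
            out["series"][(channel, component)] = comp_series
            segs, disc = segment(
                comp_series, fs, subject_id=record.subject_id,
                channel=channel, component=component,
            )
            out["segments"][(channel, component)] = segs
            out["discarded"] += disc
    return out
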