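"""Fiber-photometry processing chain.

The chain mirrors standard isosbestic-corrected bulk-calcium analysis:

1. ordinary least-squares fit of the 490 nm signal on the 405 nm control
   over the full session; the fitted control absorbs bleaching, motion
   and autofluorescence;
2. fractional fluorescence dF/F = (490 - fitted405) / fitted405 per
   sample, then z-scored over the entire session for cross-animal
   comparison;
3. trapezoidal area under the z-scored curve per arena compartment;
4. transient ("peak") event detection: a sample sequence is an event
   when dF/F exceeds the session median by 2.91 x raw MAD — with an
   *unscaled* median absolute deviation this multiplier corresponds to
   the two-sided Gaussian 95% band (2.91 x 0.6745 ~ 1.96 sd);
5. peri-event epochs from -5 s to +5 s around behavior onsets: each
   10-s window is z-scored within the window and offset so its mean over
   [-5, -4] s is zero, at most five epochs per mouse per onset label are
   averaged, and the averaged trace is summarized by a 0.5-s sliding-
   window slope and by the mean z in the 1-s bin centered on the onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import PhotometryRecording

__all__ = [
    "DffSeries",
    "EventSeries",
    "PeriEventMatrix",
    "fit_control",
    "dff",
    "control_dff",
    "compartment_auc",
    "detect_events",
    "peri_event",
    "sliding_slope",
    "summary_bin",
    "MAD_MULTIPLIER",
]

logger = logging.getLogger(__name__)

# event threshold in raw-MAD units; 2.91 x 0.6745 ~ 1.96 standard
# deviations for Gaussian data, the two-sided 95% band
MAD_MULTIPLIER = 2.91


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


@dataclass
class DffSeries:
    time_s: np.ndarray
    dff: np.ndarray
    z: np.ndarray
    slope: float
    intercept: float
    rate_hz: float


@dataclass
class EventSeries:
    times_s: np.ndarray
    threshold: float
    mad: float
    events_per_min: float
    degenerate: bool = False


@dataclass
class PeriEventMatrix:
    """Epoch x time grid of baseline-offset window z-scores."""

    time_s: np.ndarray           # window time axis, onset at 0
    epochs: np.ndarray           # (n_epochs, n_time)
    label: str
    mouse_ids: list[str]
    mean_trace: np.ndarray = field(init=False)
    summary_z: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_trace = self.epochs.mean(axis=0) if len(self.epochs) else np.zeros_like(self.time_s)
        self.summary_z = summary_bin(self.time_s, self.mean_trace)


def fit_control(rec: PhotometryRecording) -> tuple[float, float, np.ndarray]:
    """OLS fit of f490 on f405 over the session -> (slope, intercept, fitted405)."""
    f490 = np.asarray(rec.f490, dtype=float)
    f405 = np.asarray(rec.f405, dtype=float)
    if len(f490) < 2:
        raise ValueError("need at least two samples to fit the control channel")
    if np.ptp(f405) == 0:
        logger.warning("constant 405 nm control; falling back to intercept-only fit")
        return 0.0, float(f490.mean()), np.full_like(f490, f490.mean())
    slope, intercept = np.polyfit(f405, f490, 1)
    return float(slope), float(intercept), slope * f405 + intercept


def dff(rec: PhotometryRecording, fitted405: np.ndarray | None = None,
        slope: float | None = None, intercept: float | None = None) -> DffSeries:
    """Fractional dF/F against the fitted control, plus its session z-score."""
    if fitted405 is None:
        slope, intercept, fitted405 = fit_control(rec)
    fitted405 = np.asarray(fitted405, dtype=float)
    bad = np.flatnonzero(fitted405 <= 0)
    if bad.size:
        raise ValueError(f"fitted control is non-positive at sample {bad[0]}")
    d = (np.asarray(rec.f490, dtype=float) - fitted405) / fitted405
    return DffSeries(
        time_s=np.asarray(rec.time_s, dtype=float),
        dff=d,
        z=_zscore(d),
        slope=float(slope if slope is not None else np.nan),
        intercept=float(intercept if intercept is not None else np.nan),
        rate_hz=rec.rate_hz,
    )


def control_dff(rec: PhotometryRecording) -> DffSeries:
    """Artifact-control series: the 405 nm channel against its own linear trend.

    Running the identical event and peri-event analyses on this series
    checks that apparent calcium dynamics are not movement or bleaching
    artifacts; behavior-locked structure should vanish here.
    """
    f405 = np.asarray(rec.f405, dtype=float)
    t = np.asarray(rec.time_s, dtype=float)
    coef = np.polyfit(t, f405, 1)
    trend = np.polyval(coef, t)
    if np.any(trend <= 0):
        raise ValueError("405 nm trend is non-positive; cannot form control dF/F")
    d = (f405 - trend) / trend
    return DffSeries(time_s=t, dff=d, z=_zscore(d), slope=float(coef[0]),
                     intercept=float(coef[1]), rate_hz=rec.rate_hz)


def _segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where the mask is True."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    edges = np.flatnonzero(np.diff(m.astype(np.int8)))
    starts = ([0] if m[0] else []) + list(edges[~m[edges]] + 1)
    stops = list(edges[m[edges]] + 1) + ([m.size] if m[-1] else [])
    return list(zip(starts, stops))


@dataclass
class ZoneAuc:
    auc: float               # z * s over all visits
    time_in_zone_s: float    # integrated visit duration
    auc_per_s: float         # auc / time, nan-flagged when zero duration
    zero_duration: bool


def compartment_auc(series: DffSeries, masks: dict[str, np.ndarray]) -> dict[str, ZoneAuc]:
    """Trapezoidal AUC of the session z-score per arena compartment.

    ``masks`` give per-zone boolean occupancy on the photometry time
    base.  The integral is taken over each contiguous in-zone visit and
    summed; ``auc_per_s`` normalizes by the integrated visit time (the
    "mean activity" form used for correlations).
    """
    out: dict[str, ZoneAuc] = {}
    dt = 1.0 / series.rate_hz
    for zone, mask in masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != series.z.shape:
            raise ValueError(f"mask for {zone!r} does not match the series length")
        total = 0.0
        dur = 0.0
        for i0, i1 in _segments(mask):
            if i1 - i0 < 2:
                continue  # a single sample spans no time
            total += float(np.trapezoid(series.z[i0:i1], dx=dt))
            dur += (i1 - i0 - 1) * dt
        zero = dur == 0.0
        out[zone] = ZoneAuc(
            auc=total,
            time_in_zone_s=dur,
            auc_per_s=(total / dur) if not zero else float("nan"),
            zero_duration=zero,
        )
    return out


def detect_events(
    series: DffSeries,
    mad_multiplier: float = MAD_MULTIPLIER,
    min_interval_s: float = 0.5,
) -> EventSeries:
    """Threshold dF/F transients at session median + multiplier x raw MAD.

    One event per supra-threshold excursion, timestamped at the excursion
    maximum; events closer than ``min_interval_s`` to the previous
    accepted event are dropped.
    """
    d = series.dff
    if len(d) < round(series.rate_hz):
        raise ValueError("need at least one second of signal")
    med = float(np.median(d))
    mad = float(np.median(np.abs(d - med)))  # raw MAD, no consistency factor
    duration_min = len(d) / series.rate_hz / 60.0
    # MAD of 0 (constant or mostly-flat signal) degenerates the threshold
    # to the median itself; flagged, and a truly constant trace yields no
    # supra-threshold excursion at all
    degenerate = mad == 0.0
    thr = med + mad_multiplier * mad
    above = d > thr
    times = []
    last = -np.inf
    for i0, i1 in _segments(above):
        peak = i0 + int(np.argmax(d[i0:i1]))
        t = float(series.time_s[peak])
        if t - last >= min_interval_s:
            times.append(t)
            last = t
    times = np.asarray(times)
    return EventSeries(times, thr, mad, float(len(times) / duration_min), degenerate=degenerate)


def peri_event(
    series: DffSeries,
    onsets: list[tuple[float, str]],
    mouse_id: str = "",
    window_s: tuple[float, float] = (-5.0, 5.0),
    baseline_s: tuple[float, float] = (-5.0, -4.0),
    max_epochs_per_mouse: int = 5,
) -> dict[str, PeriEventMatrix]:
    """Extract, normalize and average behavior-locked epochs per label.

    Each epoch is the raw dF/F in ``window_s`` around the onset
    (nearest-sample snap, ties toward the earlier sample), z-scored
    within the window and offset so its mean over ``baseline_s`` is
    exactly zero.  Only the first ``max_epochs_per_mouse`` epochs per
    (mouse, label) are retained; onsets too close to the record edge are
    skipped with a log entry.
    """
    lo, hi = window_s
    n_lo = int(round(-lo * series.rate_hz))
    n_hi = int(round(hi * series.rate_hz))
    tgrid = np.arange(-n_lo, n_hi + 1) / series.rate_hz
    base = (tgrid >= baseline_s[0]) & (tgrid <= baseline_s[1])

    by_label: dict[str, list[np.ndarray]] = {}
    counts: dict[tuple[str, str], int] = {}
    t0 = float(series.time_s[0])
    for onset, label in sorted(onsets, key=lambda p: p[0]):
        key = (mouse_id, label)
        if counts.get(key, 0) >= max_epochs_per_mouse:
            continue
        # nearest sample; exact midpoints snap to the earlier sample
        pos = (onset - t0) * series.rate_hz
        idx = int(np.floor(pos + 0.5)) if (pos % 1) != 0.5 else int(np.floor(pos))
        if idx - n_lo < 0 or idx + n_hi >= len(series.dff):
            logger.info("skipping onset %.3f s (%s): window exceeds record", onset, label)
            continue
        w = series.dff[idx - n_lo : idx + n_hi + 1]
        wz = _zscore(w)
        wz = wz - wz[base].mean()
        by_label.setdefault(label, []).append(wz)
        counts[key] = counts.get(key, 0) + 1

    return {
        label: PeriEventMatrix(
            time_s=tgrid,
            epochs=np.vstack(eps),
            label=label,
            mouse_ids=[mouse_id] * len(eps),
        )
        for label, eps in by_label.items()
    }


def sliding_slope(time_s: np.ndarray, trace: np.ndarray, window_s: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares slope of the trace in a centered sliding window.

    Edges where the full window does not fit are truncated.  Returns
    (window-center times, slopes).
    """
    time_s = np.asarray(time_s, dtype=float)
    trace = np.asarray(trace, dtype=float)
    dt = time_s[1] - time_s[0]
    half = int(round(window_s / (2 * dt)))
    k = 2 * half + 1
    if len(trace) < k:
        raise ValueError("trace shorter than the sliding window")
    # slope of OLS line on a uniform grid: dot with centered weights
    x = (np.arange(k) - half) * dt
    w = x / np.sum(x * x)
    slopes = np.convolve(trace, w[::-1], mode="valid")
    return time_s[half : len(time_s) - half], slopes


def summary_bin(time_s: np.ndarray, trace: np.ndarray,
                bin_s: tuple[float, float] = (-0.5, 0.5)) -> float:
    """Mean of the trace over the 1-s bin centered on the onset."""
    m = (np.asarray(time_s) >= bin_s[0]) & (np.asarray(time_s) <= bin_s[1])
    if not m.any():
        raise ValueError("trace does not cover the summary bin")
    return float(np.asarray(trace)[m].mean())
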