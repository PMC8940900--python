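"""Patch-clamp feature extraction and putative-dopamine classification.

Cell-attached spike detection runs on a high-pass filtered trace with a
robust (MAD-based) threshold; spikes are timestamped at the negative
trough of each crossing with a short refractory period.  Whole-cell
features follow the standard step-protocol definitions: excitability as
spikes per current step, rheobase as the smallest step eliciting at
least one spike, Ih as steady-state minus instantaneous current under
hyperpolarizing voltage steps (inward negative), and sag as the
repolarization from the voltage minimum toward steady state during a
hyperpolarizing current step.

Putative dopamine neurons are units with firing rate between 1 and
10 Hz and spike-onset-to-trough latency strictly greater than 1.1 ms;
only such neurons enter the per-mouse averages by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .core import SweepSet
from .ephys_sim import EXC_COMMANDS_PA

__all__ = [
    "detect_spikes",
    "trough_latency_ms",
    "firing_rate",
    "classify_putative_da",
    "excitability_curve",
    "rheobase",
    "ih_amplitude",
    "sag_metrics",
    "per_mouse_mean",
    "NeuronFeatures",
    "DA_RATE_RANGE_HZ",
    "DA_TROUGH_LATENCY_MS",
]

logger = logging.getLogger(__name__)

DA_RATE_RANGE_HZ = (1.0, 10.0)
DA_TROUGH_LATENCY_MS = 1.1  # strict lower bound ("superior to 1.1 ms")


@dataclass
class NeuronFeatures:
    mouse_id: str
    firing_hz: float | None = None
    trough_latency_ms: float | None = None
    is_putative_da: bool | None = None
    spikes_per_step: dict[float, int] | None = None
    rheobase_pA: float | None = None
    ih_amp_pA: dict[float, float] | None = None
    sag_amp_mV: float | None = None
    sag_ratio: float | None = None


def _highpass(trace: np.ndarray, rate_hz: float, cutoff_hz: float) -> np.ndarray:
    sos = butter(3, cutoff_hz, btype="highpass", fs=rate_hz, output="sos")
    return sosfiltfilt(sos, trace)


def detect_spikes(
    trace: np.ndarray,
    rate_hz: float,
    threshold_sd: float = 4.5,
    highpass_hz: float = 100.0,
    smooth_ms: float = 0.5,
    refractory_ms: float = 2.0,
) -> np.ndarray:
    """Spike trough times from a cell-attached trace.

    The trace is high-pass filtered, then smoothed with a Gaussian
    kernel roughly matched to the spike trough width — the smoothing
    narrows the noise bandwidth so that a ``threshold_sd`` x robust SD
    (1.4826 x MAD) threshold crosses on noise only rarely while the
    much wider spike deflection survives.  Detection is on the
    negative-going phase (the larger lobe of the extracellular
    waveform).  A flat trace yields no spikes.
    """
    trace = np.asarray(trace, dtype=float)
    if len(trace) < rate_hz:
        raise ValueError("need at least one second of trace")
    filt = _highpass(trace, rate_hz, highpass_hz)
    if smooth_ms > 0:
        sigma = smooth_ms / 1000.0 * rate_hz
        half = int(np.ceil(4 * sigma))
        k = np.exp(-0.5 * ((np.arange(-half, half + 1)) / sigma) ** 2)
        filt = np.convolve(filt, k / k.sum(), mode="same")
    mad = np.median(np.abs(filt - np.median(filt)))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        return np.array([])
    thr = threshold_sd * robust_sd
    below = filt < -thr
    if not below.any():
        return np.array([])
    # one spike per sub-threshold excursion, at the extremum
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = ([0] if below[0] else []) + list(edges[~below[edges]] + 1)
    stops = list(edges[below[edges]] + 1) + ([below.size] if below[-1] else [])
    refr = refractory_ms / 1000.0
    times = []
    last = -np.inf
    for i0, i1 in zip(starts, stops):
        t = (i0 + int(np.argmin(filt[i0:i1]))) / rate_hz
        if t - last >= refr:
            times.append(t)
            last = t
    return np.asarray(times)


def trough_latency_ms(
    trace: np.ndarray,
    rate_hz: float,
    spike_times_s: np.ndarray,
    onset_frac: float = 0.1,
) -> float:
    """Mean latency from waveform beginning to the negative trough.

    The waveforms around each detected trough are averaged; the
    beginning is where the average first rises above ``onset_frac`` of
    the positive-peak height ahead of the trough.
    """
    spike_times_s = np.asarray(spike_times_s)
    if spike_times_s.size == 0:
        return float("nan")
    pre = int(round(0.004 * rate_hz))   # 4 ms context before the trough
    post = int(round(0.002 * rate_hz))
    segs = []
    for t in spike_times_s:
        i = int(round(t * rate_hz))
        if i - pre >= 0 and i + post < len(trace):
            segs.append(trace[i - pre : i + post])
    if not segs:
        return float("nan")
    avg = np.mean(segs, axis=0)
    trough_i = pre  # by construction the trough sits at the center index
    pos_seg = avg[:trough_i]
    if pos_seg.size == 0 or pos_seg.max() <= 0:
        return float("nan")
    peak_i = int(np.argmax(pos_seg))
    level = onset_frac * pos_seg[peak_i]
    onset_i = peak_i
    while onset_i > 0 and avg[onset_i - 1] > level:
        onset_i -= 1
    return (trough_i - onset_i) / rate_hz * 1000.0


def firing_rate(spike_times_s: np.ndarray, duration_s: float) -> float:
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return len(spike_times_s) / duration_s


def classify_putative_da(firing_hz: float, trough_latency_ms: float) -> bool:
    """Band rule: 1 <= rate <= 10 Hz and trough latency strictly > 1.1 ms."""
    if not (np.isfinite(firing_hz) and np.isfinite(trough_latency_ms)):
        return False
    lo, hi = DA_RATE_RANGE_HZ
    return bool(lo <= firing_hz <= hi and trough_latency_ms > DA_TROUGH_LATENCY_MS)


def _count_spikes_cc(trace: np.ndarray, rate_hz: float, on_s: float, off_s: float,
                     thr_mV: float = 0.0) -> int:
    """Upward threshold crossings of a rendered current-clamp trace."""
    i0 = int(round(on_s * rate_hz))
    i1 = int(round(off_s * rate_hz))
    seg = trace[i0:i1] > thr_mV
    return int(np.count_nonzero(seg[1:] & ~seg[:-1]) + (1 if seg[:1].any() else 0))


def excitability_curve(sweeps: SweepSet) -> dict[float, int]:
    """Spike count within the step window per command current."""
    if sweeps.protocol != "excitability":
        raise ValueError("excitability_curve requires the excitability protocol")
    missing = sorted(set(EXC_COMMANDS_PA) - set(np.asarray(sweeps.commands)))
    if missing:
        raise ValueError(f"missing command steps: {missing}")
    return {
        float(cmd): _count_spikes_cc(sweeps.traces[j], sweeps.rate_hz,
                                     sweeps.step_on_s, sweeps.step_off_s)
        for j, cmd in enumerate(sweeps.commands)
    }


def rheobase(curve: dict[float, int]) -> float | None:
    """Smallest command current with at least one spike, or None."""
    firing = [cmd for cmd, n in curve.items() if n >= 1]
    return min(firing) if firing else None


def ih_amplitude(
    sweeps: SweepSet,
    instantaneous_window_s: tuple[float, float] = (0.020, 0.060),
    steady_frac: float = 0.1,
) -> dict[float, float]:
    """Ih per voltage step: steady-state minus instantaneous current (pA).

    Instantaneous current is averaged over a post-transient window after
    step onset (default 20-60 ms); steady state over the final
    ``steady_frac`` of the step.  Inward currents are negative.
    """
    if sweeps.protocol != "ih_vclamp":
        raise ValueError("ih_amplitude requires the ih_vclamp protocol")
    fs = sweeps.rate_hz
    dur = sweeps.step_off_s - sweeps.step_on_s
    a = int(round((sweeps.step_on_s + instantaneous_window_s[0]) * fs))
    b = int(round((sweeps.step_on_s + instantaneous_window_s[1]) * fs))
    c = int(round((sweeps.step_off_s - steady_frac * dur) * fs))
    d = int(round(sweeps.step_off_s * fs))
    if b > sweeps.traces.shape[1] or d > sweeps.traces.shape[1] or a >= b or c >= d:
        raise ValueError("measurement windows fall outside the sweep")
    out = {}
    for j, cmd in enumerate(sweeps.commands):
        inst = float(sweeps.traces[j, a:b].mean())
        ss = float(sweeps.traces[j, c:d].mean())
        out[float(cmd)] = ss - inst
    return out


def sag_metrics(
    trace: np.ndarray,
    rate_hz: float,
    step_on_s: float,
    step_off_s: float,
    steady_frac: float = 0.1,
    target_band_mV: tuple[float, float] = (-90.0, -70.0),
) -> tuple[float, float]:
    """(sag amplitude mV, sag ratio) of a hyperpolarizing current sweep.

    V_peak is the minimum during the step, V_ss the mean over its final
    fraction; sag amplitude = V_ss - V_peak and sag ratio =
    (V_ss - V_peak) / (V_baseline - V_peak).  A peak outside the ~-80 mV
    target band logs a warning but the measurement proceeds.
    """
    i0 = int(round(step_on_s * rate_hz))
    i1 = int(round(step_off_s * rate_hz))
    if i0 <= 0 or i1 > len(trace):
        raise ValueError("step window falls outside the trace")
    v_base = float(np.mean(trace[: i0]))
    step = trace[i0:i1]
    v_peak = float(step.min())
    v_ss = float(step[int(round((1 - steady_frac) * len(step))):].mean())
    if not target_band_mV[0] <= v_peak <= target_band_mV[1]:
        logger.warning("sag peak %.1f mV outside target band %s", v_peak, target_band_mV)
    amp = v_ss - v_peak
    denom = v_base - v_peak
    ratio = amp / denom if denom != 0 else float("nan")
    return amp, ratio


def per_mouse_mean(
    neurons: pd.DataFrame,
    features: list[str] | None = None,
    require_putative_da: bool = True,
) -> pd.DataFrame:
    """Unweighted per-mouse arithmetic mean of neuron-level features.

    ``neurons`` must carry ``mouse_id`` and, when filtering,
    ``is_putative_da``; mice left with no qualifying neurons are dropped
    with a log entry.
    """
    df = neurons
    if require_putative_da:
        if "is_putative_da" not in df.columns:
            raise ValueError("need an is_putative_da column to filter")
        kept = df[df["is_putative_da"].astype(bool)]
        dropped = set(df["mouse_id"]) - set(kept["mouse_id"])
        for m in sorted(dropped):
            logger.info("mouse %s excluded: no putative dopamine neurons", m)
        df = kept
    if features is None:
        features = [c for c in df.columns
                    if c not in ("mouse_id", "is_putative_da") and pd.api.types.is_numeric_dtype(df[c])]
    return df.groupby("mouse_id", sort=True)[features].mean().reset_index()
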