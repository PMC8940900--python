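"""Two-channel fiber-photometry signal simulator.

Generates decimated 490 nm (calcium-dependent) and 405 nm (isosbestic
control) channels at a common rate (default 381 Hz) with the artifact
structure the correction stage is designed to remove:

* multiplicative photobleaching, modeled as a double-exponential decay
  with per-channel amplitude but a shared shape (bleaching of the same
  fluorophore under both excitation wavelengths);
* an additive motion artifact shared between channels, scaled per
  channel in proportion to its baseline brightness (artifacts scale with
  collected light);
* calcium transients only in the 490 channel, placed by an
  inhomogeneous Poisson process whose rate increases while the animal
  occupies a designated zone (e.g., the plus-maze open arms), convolved
  with a double-exponential indicator kernel
  ``k(t) = A (1 - exp(-t/tau_r)) exp(-t/tau_d)``.

True transient times are retained for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .cohort import SENSOR_KERNELS
from .core import PhotometryRecording, Trajectory

__all__ = ["PhotometrySimParams", "PhotometrySim", "gen_photometry", "transient_kernel", "kernel_peak"]


def transient_kernel(tau_r_s: float, tau_d_s: float, rate_hz: float, amp: float = 1.0) -> np.ndarray:
    """Sampled indicator kernel, truncated at 8 decay constants."""
    t = np.arange(0.0, 8.0 * tau_d_s, 1.0 / rate_hz)
    return amp * (1.0 - np.exp(-t / tau_r_s)) * np.exp(-t / tau_d_s)


def kernel_peak(tau_r_s: float, tau_d_s: float, amp: float = 1.0) -> float:
    """Analytic maximum of the kernel, at t* = tau_r * ln(1 + tau_d/tau_r)."""
    t_star = tau_r_s * np.log1p(tau_d_s / tau_r_s)
    return float(amp * (1.0 - np.exp(-t_star / tau_r_s)) * np.exp(-t_star / tau_d_s))


@dataclass(frozen=True)
class PhotometrySimParams:
    rate_hz: float = 381.0
    baseline_490: float = 100.0
    baseline_405: float = 60.0
    # double-exponential bleach: 1 - a1(1-exp(-t/tau1)) - a2(1-exp(-t/tau2))
    bleach_a1: float = 0.08
    bleach_tau1_s: float = 60.0
    bleach_a2: float = 0.15
    bleach_tau2_s: float = 600.0
    motion_amp: float = 2.0       # a.u. in the 490 channel
    motion_cut_hz: float = 2.0    # low-pass corner of the artifact process
    noise_sd: float = 0.3         # white measurement noise per channel, a.u.
    transient_amp_frac: float = 0.06   # transient peak height / baseline
    transient_amp_cv: float = 0.3      # lognormal amplitude jitter
    tau_r_s: float = 0.18
    tau_d_s: float = 1.4

    @staticmethod
    def for_sensor(sensor: str, **overrides) -> "PhotometrySimParams":
        tau_r, tau_d = SENSOR_KERNELS[sensor]
        return PhotometrySimParams(tau_r_s=tau_r, tau_d_s=tau_d, **overrides)


@dataclass
class PhotometrySim:
    recording: PhotometryRecording
    true_event_times_s: np.ndarray
    in_zone: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


def _bleach(t: np.ndarray, p: PhotometrySimParams) -> np.ndarray:
    return (
        1.0
        - p.bleach_a1 * (1.0 - np.exp(-t / p.bleach_tau1_s))
        - p.bleach_a2 * (1.0 - np.exp(-t / p.bleach_tau2_s))
    )


def _motion(n: int, p: PhotometrySimParams, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean low-pass artifact via single-pole smoothing of white noise."""
    if p.motion_amp == 0:
        return np.zeros(n)
    alpha = np.exp(-2.0 * np.pi * p.motion_cut_hz / p.rate_hz)
    w = rng.standard_normal(n)
    m = lfilter([1.0 - alpha], [1.0, -alpha], w)
    m -= m.mean()
    sd = m.std()
    if sd > 0:
        m *= p.motion_amp / sd
    return m


def gen_photometry(
    traj: Trajectory,
    base_rate_per_min: float,
    zone_gain_per_min: float = 0.0,
    zone: str | None = None,
    params: PhotometrySimParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    sync_events: list[tuple[float, str]] | None = None,
    event_times_s: np.ndarray | None = None,
) -> PhotometrySim:
    """Simulate a two-channel recording aligned to a trajectory.

    The transient rate is ``base_rate_per_min`` everywhere plus
    ``zone_gain_per_min`` while the trajectory's center point is inside
    ``zone``.  ``event_times_s`` bypasses the Poisson draw and places
    transients at the given times (useful for worked examples).  The
    recording covers the trajectory duration.
    """
    p = params or PhotometrySimParams()
    if p.rate_hz <= 0:
        raise ValueError("sampling rate must be positive")
    rng = np.random.default_rng(seed)

    duration = traj.duration_s
    n = int(round(duration * p.rate_hz))
    t = np.arange(n) / p.rate_hz

    # zone indicator resampled to the photometry time base (nearest sample)
    if zone is not None:
        idx = np.clip(np.round(t * (1.0 / traj.dt_s)).astype(int), 0, len(traj) - 1)
        in_zone = np.asarray(traj.arena.in_zone(zone, traj.x_cm[idx], traj.y_cm[idx]))
    else:
        in_zone = np.zeros(n, dtype=bool)

    if event_times_s is not None:
        event_idx = np.round(np.asarray(event_times_s, dtype=float) * p.rate_hz).astype(int)
        event_idx = event_idx[(event_idx >= 0) & (event_idx < n)]
    else:
        rate_hz_t = (base_rate_per_min + zone_gain_per_min * in_zone) / 60.0
        spikes = rng.random(n) < rate_hz_t / p.rate_hz
        event_idx = np.flatnonzero(spikes)
    event_times = t[event_idx]

    transients = np.zeros(n)
    if event_idx.size:
        kern = transient_kernel(p.tau_r_s, p.tau_d_s, p.rate_hz)
        if p.transient_amp_cv > 0:
            jitter = rng.lognormal(
                mean=-0.5 * np.log1p(p.transient_amp_cv**2),
                sigma=np.sqrt(np.log1p(p.transient_amp_cv**2)),
                size=event_idx.size,
            )
        else:
            jitter = np.ones(event_idx.size)
        amps = p.baseline_490 * p.transient_amp_frac * jitter
        impulses = np.zeros(n)
        np.add.at(impulses, event_idx, amps)
        transients = np.convolve(impulses, kern)[:n]

    bleach = _bleach(t, p)
    motion = _motion(n, p, rng)
    gain_405 = p.baseline_405 / p.baseline_490  # artifact scales with brightness

    f490 = (p.baseline_490 + transients) * bleach + motion + p.noise_sd * rng.standard_normal(n)
    f405 = p.baseline_405 * bleach + motion * gain_405 + p.noise_sd * rng.standard_normal(n)

    rec = PhotometryRecording(
        time_s=t,
        f490=f490,
        f405=f405,
        rate_hz=p.rate_hz,
        sync_events=list(sync_events or []),
    )
    return PhotometrySim(recording=rec, true_event_times_s=event_times, in_zone=in_zone)
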