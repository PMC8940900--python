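"""Synthetic patch-clamp data: membrane model and cell-attached traces.

The membrane is a single-compartment leaky integrate-and-fire neuron
augmented with one hyperpolarization-activated (Ih / HCN) conductance:

    C dV/dt = -g_L (V - E_L) - g_h x (V - E_h) + I_inj
    dx/dt   = (x_inf(V) - x) / tau_h,   x_inf(V) = 1 / (1 + exp((V - V_half)/k))

with spike-and-reset at V_th.  This is the minimal model exhibiting every
feature the extraction stage measures: rheobase, an excitability curve,
voltage sag under hyperpolarizing current, and the slow inward Ih current
under hyperpolarizing voltage steps.

Units: pF, nS, mV, pA, ms (so pA/pF = mV/ms).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .core import SweepSet

__all__ = [
    "MembraneParams",
    "x_inf",
    "steady_state_voltage",
    "simulate_current_clamp",
    "gen_step_protocols",
    "gen_cell_attached",
    "spike_waveform",
    "EXC_COMMANDS_PA",
    "IH_COMMANDS_MV",
]

# whole-cell step protocols: 1 s current steps -100..280 pA in 20 pA
# increments; 3 s voltage steps -120..-60 mV in 10 mV increments from a
# -60 mV holding potential
EXC_COMMANDS_PA = np.arange(-100, 281, 20, dtype=float)
IH_COMMANDS_MV = np.arange(-120, -59, 10, dtype=float)

SPIKE_PAINT_MV = 20.0  # rendered action-potential peak in current clamp


@dataclass(frozen=True)
class MembraneParams:
    C_pF: float = 100.0
    g_L_nS: float = 5.0
    E_L_mV: float = -60.0
    V_th_mV: float = -40.0
    V_reset_mV: float = -50.0
    E_h_mV: float = -30.0
    g_h_nS: float = 2.0
    V_half_mV: float = -85.0
    k_mV: float = 6.0
    tau_h_ms: float = 400.0

    def validate(self) -> None:
        for k, v in asdict(self).items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite membrane parameter {k}={v}")
        if self.g_L_nS <= 0 or self.C_pF <= 0 or self.tau_h_ms <= 0:
            raise ValueError("g_L, C and tau_h must be positive")


def x_inf(v_mV, params: MembraneParams):
    """Steady-state Ih activation (increases with hyperpolarization)."""
    return 1.0 / (1.0 + np.exp((np.asarray(v_mV, dtype=float) - params.V_half_mV) / params.k_mV))


def steady_state_voltage(params: MembraneParams, i_pA: float) -> float:
    """Root of the current-balance equation for a constant subthreshold current."""
    from scipy.optimize import brentq

    def balance(v):
        return (
            -params.g_L_nS * (v - params.E_L_mV)
            - params.g_h_nS * x_inf(v, params) * (v - params.E_h_mV)
            + i_pA
        )

    return float(brentq(balance, -200.0, params.V_th_mV - 1e-9))


def simulate_current_clamp(
    params: MembraneParams,
    commands_pA: np.ndarray,
    step_on_s: float = 0.2,
    step_dur_s: float = 1.0,
    post_s: float = 0.3,
    dt_ms: float = 0.05,
    holding_pA: float = 0.0,
    noise_sd_mV: float = 0.0,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[np.ndarray, float, list[np.ndarray]]:
    """Integrate all sweeps of a current-step family in parallel.

    Returns (traces, rate_hz, spike_times_per_sweep); spikes are rendered
    as one sample at +20 mV followed by reset.
    """
    params.validate()
    if dt_ms > 0.1:
        raise ValueError("integration step must be <= 0.1 ms")
    commands = np.asarray(commands_pA, dtype=float)
    n_sw = len(commands)
    n = int(round((step_on_s + step_dur_s + post_s) * 1000.0 / dt_ms))
    on = int(round(step_on_s * 1000.0 / dt_ms))
    off = int(round((step_on_s + step_dur_s) * 1000.0 / dt_ms))

    v = np.full(n_sw, params.E_L_mV)
    # start from the holding-current fixed point
    v0 = steady_state_voltage(params, holding_pA)
    v[:] = v0
    x = x_inf(v0, params) * np.ones(n_sw)

    gl, c = params.g_L_nS, params.C_pF
    gh, eh = params.g_h_nS, params.E_h_mV
    el, vth, vreset = params.E_L_mV, params.V_th_mV, params.V_reset_mV
    relax = 1.0 - np.exp(-dt_ms / params.tau_h_ms)

    traces = np.empty((n_sw, n))
    spikes: list[list[float]] = [[] for _ in range(n_sw)]
    for i in range(n):
        i_inj = np.where((i >= on) & (i < off), commands, holding_pA)
        dv = (-gl * (v - el) - gh * x * (v - eh) + i_inj) * (dt_ms / c)
        v = v + dv
        x = x + (x_inf(v, params) - x) * relax
        fired = v >= vth
        if fired.any():
            t_ms = i * dt_ms
            for j in np.flatnonzero(fired):
                spikes[j].append(t_ms / 1000.0)
            traces[fired, i] = SPIKE_PAINT_MV
            traces[~fired, i] = v[~fired]
            v = np.where(fired, vreset, v)
        else:
            traces[:, i] = v
    rate_hz = 1000.0 / dt_ms
    if noise_sd_mV > 0:
        rng = np.random.default_rng(seed)
        traces = traces + rng.normal(0.0, noise_sd_mV, traces.shape)
    return traces, rate_hz, [np.asarray(s) for s in spikes]


def _vclamp_current(params: MembraneParams, commands_mV: np.ndarray, hold_mV: float,
                    step_on_s: float, step_dur_s: float, post_s: float,
                    rate_hz: float) -> np.ndarray:
    """Analytic voltage-clamp currents: gating relaxes exponentially per segment."""
    n = int(round((step_on_s + step_dur_s + post_s) * rate_hz))
    t = np.arange(n) / rate_hz
    tau_s = params.tau_h_ms / 1000.0
    x0 = float(x_inf(hold_mV, params))
    traces = np.empty((len(commands_mV), n))
    for j, vc in enumerate(commands_mV):
        v = np.full(n, hold_mV)
        step = (t >= step_on_s) & (t < step_on_s + step_dur_s)
        v[step] = vc
        x = np.full(n, x0)
        xs = float(x_inf(vc, params))
        ts = t[step] - step_on_s
        x[step] = xs + (x0 - xs) * np.exp(-ts / tau_s)
        # after the step, relax back toward the holding-level activation
        after = t >= step_on_s + step_dur_s
        if after.any():
            x_end = xs + (x0 - xs) * np.exp(-step_dur_s / tau_s)
            ta = t[after] - (step_on_s + step_dur_s)
            x[after] = x0 + (x_end - x0) * np.exp(-ta / tau_s)
        traces[j] = params.g_L_nS * (v - params.E_L_mV) + params.g_h_nS * x * (v - params.E_h_mV)
    return traces


def _sag_command_pA(params: MembraneParams, target_mV: float = -80.0) -> float:
    """Current step whose early voltage minimum lands near the target.

    The instantaneous (pre-Ih-relaxation) balance gives the starting
    guess; the value matters only up to the out-of-band warning in the
    extraction stage, so no further refinement is applied here.
    """
    x0 = float(x_inf(params.E_L_mV, params))
    return float(
        params.g_L_nS * (target_mV - params.E_L_mV)
        + params.g_h_nS * x0 * (target_mV - params.E_h_mV)
    )


def gen_step_protocols(
    params: MembraneParams,
    protocol: str,
    seed: int | np.random.SeedSequence | None = None,
    noise_sd: float = 0.0,
    dt_ms: float = 0.1,
) -> SweepSet:
    """Simulate one of the whole-cell step protocols as a SweepSet.

    ``excitability``: 1 s current steps, -100..280 pA / 20 pA (current clamp).
    ``ih_vclamp``: 3 s voltage steps, -120..-60 mV / 10 mV from -60 mV holding.
    ``sag_cclamp``: a single 1 s hyperpolarizing step sized to pull the
    voltage minimum to about -80 mV.
    """
    params.validate()
    if protocol == "excitability":
        traces, rate, _ = simulate_current_clamp(
            params, EXC_COMMANDS_PA, step_on_s=0.2, step_dur_s=1.0, post_s=0.3,
            dt_ms=dt_ms, noise_sd_mV=noise_sd, seed=seed,
        )
        return SweepSet("excitability", EXC_COMMANDS_PA.copy(), traces, rate, 0.2, 1.2)
    if protocol == "ih_vclamp":
        rate = 1000.0 / dt_ms
        traces = _vclamp_current(params, IH_COMMANDS_MV, -60.0, 0.5, 3.0, 0.5, rate)
        if noise_sd > 0:
            rng = np.random.default_rng(seed)
            traces = traces + rng.normal(0.0, noise_sd, traces.shape)
        return SweepSet("ih_vclamp", IH_COMMANDS_MV.copy(), traces, rate, 0.5, 3.5)
    if protocol == "sag_cclamp":
        i_cmd = _sag_command_pA(params)
        traces, rate, _ = simulate_current_clamp(
            params, np.array([i_cmd]), step_on_s=0.2, step_dur_s=1.0, post_s=0.3,
            dt_ms=dt_ms, noise_sd_mV=noise_sd, seed=seed,
        )
        return SweepSet("sag_cclamp", np.array([i_cmd]), traces, rate, 0.2, 1.2)
    raise ValueError(f"unknown protocol {protocol!r}")


def spike_waveform(
    rate_hz: float,
    trough_latency_ms: float = 1.5,
    amp: float = 1.0,
    pos_frac: float = 0.6,
) -> np.ndarray:
    """Stereotyped biphasic extracellular waveform.

    A positive deflection beginning at t = 0 followed by a negative
    trough at ``trough_latency_ms`` (the latency the putative-dopamine
    classification measures).
    """
    if trough_latency_ms <= 0.2:
        raise ValueError("trough latency must exceed the positive-phase width")
    dt_ms = 1000.0 / rate_hz
    t = np.arange(0.0, trough_latency_ms + 2.0, dt_ms)
    pos = pos_frac * amp * np.exp(-0.5 * ((t - 0.25) / 0.12) ** 2)
    neg = -amp * np.exp(-0.5 * ((t - trough_latency_ms) / 0.25) ** 2)
    return pos + neg


def gen_cell_attached(
    rate_hz: float,
    duration_s: float,
    noise_sd: float = 0.125,
    seed: int | np.random.SeedSequence | None = None,
    sample_rate_hz: float = 10_000.0,
    gamma_shape: float = 5.0,
    trough_latency_ms: float = 1.5,
    spike_amp: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Simulate a cell-attached recording as (trace, true_spike_times_s, fs).

    Spikes are placed by a gamma renewal process (shape ``gamma_shape``,
    mean interval ``1/rate_hz``) and summed as stereotyped waveforms on
    additive Gaussian noise.  ``rate_hz = 0`` yields pure noise.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s * sample_rate_hz))
    if n > 50_000_000:
        raise ValueError("requested trace is unreasonably long")
    rng = np.random.default_rng(seed)
    trace = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)

    spike_times = np.array([])
    if rate_hz > 0:
        mean_isi = 1.0 / rate_hz
        n_draw = int(duration_s * rate_hz * 2 + 20)
        isis = rng.gamma(gamma_shape, mean_isi / gamma_shape, size=n_draw)
        times = np.cumsum(isis) + rng.uniform(0.0, mean_isi)
        spike_times = times[times < duration_s]
        wf = spike_waveform(sample_rate_hz, trough_latency_ms, amp=spike_amp)
        # spike times refer to the negative trough (what detection reports)
        lat_n = int(round(trough_latency_ms / 1000.0 * sample_rate_hz))
        for ts in spike_times:
            i0 = int(round(ts * sample_rate_hz)) - lat_n
            w0 = max(0, -i0)
            seg = min(len(wf), n - i0)
            if seg > w0:
                trace[i0 + w0 : i0 + seg] += wf[w0:seg]
    return trace, spike_times, sample_rate_hz
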