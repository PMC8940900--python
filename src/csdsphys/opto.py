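"""Pulse-train timing arithmetic for optogenetic stimulation patterns.

The stimulation protocols themselves (lasers, opsins) are out of scope;
these helpers only convert a pulse-train description into its implied
frequencies, e.g. 40 ms pulses separated by 10 ms light-off give a
within-train rate of 20 Hz, and one train every 5 s repeats at 0.2 Hz.
"""

from __future__ import annotations

__all__ = ["within_train_hz", "train_rate_hz", "duty_cycle"]


def within_train_hz(pulse_width_s: float, gap_s: float) -> float:
    """Pulse repetition frequency inside a train: 1 / (pulse + gap)."""
    period = pulse_width_s + gap_s
    if period <= 0:
        raise ValueError("pulse width + gap must be positive")
    return 1.0 / period


def train_rate_hz(train_period_s: float) -> float:
    """Train repetition rate: one train per period."""
    if train_period_s <= 0:
        raise ValueError("train period must be positive")
    return 1.0 / train_period_s


def duty_cycle(pulse_width_s: float, gap_s: float) -> float:
    """Fraction of within-train time the light is on."""
    period = pulse_width_s + gap_s
    if period <= 0:
        raise ValueError("pulse width + gap must be positive")
    return pulse_width_s / period
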