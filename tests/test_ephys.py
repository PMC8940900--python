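"""Spike detection, unit classification, feature extraction, aggregation."""

import numpy as np
import pandas as pd
import pytest

from csdsphys.cohort import gen_cohort, mouse_seeds
from csdsphys.ephys import (
    classify_putative_da,
    detect_spikes,
    firing_rate,
    per_mouse_mean,
    rheobase,
    sag_metrics,
    trough_latency_ms,
)
from csdsphys.ephys_sim import gen_cell_attached


class TestDetectSpikes:
    def test_false_positive_rate_on_pure_noise(self):
        fp = []
        for seed in range(3):
            trace, _, fs = gen_cell_attached(0.0, 60.0, noise_sd=1.0, seed=seed)
            fp.append(len(detect_spikes(trace, fs)) / 60.0)
        assert max(fp) < 0.2

    def test_recall_and_precision_at_snr8(self):
        trace, truth, fs = gen_cell_attached(4.0, 60.0, noise_sd=0.125, seed=7)
        det = detect_spikes(trace, fs)
        matched = sum(1 for t in det if np.min(np.abs(truth - t)) <= 0.001)
        assert matched / len(truth) >= 0.99   # recall
        assert matched / len(det) >= 0.99     # precision

    def test_single_spike_in_minimal_trace(self):
        trace, truth, fs = gen_cell_attached(1.0, 1.0, noise_sd=0.05, seed=2)
        assert len(truth) == 1
        det = detect_spikes(trace, fs)
        assert len(det) == 1

    def test_flat_trace_yields_no_spikes(self):
        assert detect_spikes(np.zeros(20000), 10_000.0).size == 0

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes(np.zeros(100), 10_000.0)


class TestRateAndClassification:
    def test_firing_rate_definition(self):
        assert firing_rate(np.array([]), 60.0) == 0.0
        assert firing_rate(np.zeros(240), 60.0) == pytest.approx(4.0)
        with pytest.raises(ValueError):
            firing_rate(np.zeros(3), 0.0)

    def test_extracted_rate_matches_renewal_generator(self):
        trace, truth, fs = gen_cell_attached(4.0, 60.0, seed=11)
        rate = firing_rate(detect_spikes(trace, fs), 60.0)
        assert rate == pytest.approx(len(truth) / 60.0, abs=0.15)

    @pytest.mark.parametrize("rate,lat,want", [
        (4.0, 1.5, True),
        (0.5, 1.5, False),     # too slow
        (12.0, 1.5, False),    # too fast
        (4.0, 1.1, False),     # boundary is strict
        (4.0, 0.9, False),
        (1.0, 1.2, True),      # rate band is inclusive
        (10.0, 1.2, True),
    ])
    def test_putative_da_rule(self, rate, lat, want):
        assert classify_putative_da(rate, lat) is want

    def test_rule_is_a_band_not_monotone(self):
        """Exhaustive grid: acceptance is non-monotone in firing rate."""
        rates = [0.5, 1.0, 5.0, 10.0, 11.0]
        accepted = [classify_putative_da(r, 1.5) for r in rates]
        assert accepted == [False, True, True, True, False]

    def test_latency_measured_from_generator_waveform(self):
        for lat, want_da in ((1.5, True), (0.8, False)):
            trace, _, fs = gen_cell_attached(4.0, 30.0, noise_sd=0.05, seed=5,
                                             trough_latency_ms=lat)
            det = detect_spikes(trace, fs)
            measured = trough_latency_ms(trace, fs, det)
            assert measured == pytest.approx(lat, abs=0.25)
            assert classify_putative_da(firing_rate(det, 30.0), measured) is want_da


class TestRheobase:
    def test_all_silent_is_undefined(self):
        assert rheobase({c: 0 for c in np.arange(-100, 281, 20)}) is None

    def test_no_positivity_assumption(self):
        curve = {-100.0: 0, -20.0: 1, 0.0: 0, 20.0: 2}
        assert rheobase(curve) == -20.0


class TestSag:
    def test_hand_built_trace(self):
        """Baseline -60, peak -80, steady -74: amplitude 6 mV, ratio 0.30."""
        fs = 10_000.0
        pre = np.full(int(0.2 * fs), -60.0)
        step = np.full(int(1.0 * fs), -74.0)
        step[: int(0.1 * fs)] = np.linspace(-60, -80, int(0.1 * fs))
        step[int(0.1 * fs): int(0.3 * fs)] = np.linspace(-80, -74, int(0.2 * fs))
        trace = np.concatenate([pre, step, np.full(int(0.2 * fs), -60.0)])
        amp, ratio = sag_metrics(trace, fs, 0.2, 1.2)
        assert amp == pytest.approx(6.0, abs=0.05)
        assert ratio == pytest.approx(0.30, abs=0.01)

    def test_out_of_band_peak_warns_but_proceeds(self, caplog):
        fs = 1000.0
        trace = np.concatenate([np.full(200, -60.0), np.full(1000, -65.0), np.full(200, -60.0)])
        with caplog.at_level("WARNING"):
            amp, _ = sag_metrics(trace, fs, 0.2, 1.2)
        assert "target band" in caplog.text
        assert amp == pytest.approx(0.0, abs=1e-9)


class TestPerMouseMean:
    def test_single_neuron_identity_and_mean(self):
        df = pd.DataFrame({
            "mouse_id": ["a", "b", "b", "b"],
            "firing_hz": [3.0, 2.0, 4.0, 6.0],
            "is_putative_da": [True] * 4,
        })
        out = per_mouse_mean(df)
        assert out.set_index("mouse_id").loc["a", "firing_hz"] == 3.0
        assert out.set_index("mouse_id").loc["b", "firing_hz"] == pytest.approx(4.0)

    def test_permutation_invariance(self):
        df = pd.DataFrame({
            "mouse_id": ["a", "a", "a"],
            "firing_hz": [2.0, 4.0, 6.0],
            "is_putative_da": [True] * 3,
        })
        shuffled = df.sample(frac=1.0, random_state=1)
        pd.testing.assert_frame_equal(per_mouse_mean(df), per_mouse_mean(shuffled))

    def test_non_da_neurons_excluded_by_default(self):
        df = pd.DataFrame({
            "mouse_id": ["a", "a", "b"],
            "firing_hz": [2.0, 100.0, 5.0],
            "is_putative_da": [True, False, False],
        })
        out = per_mouse_mean(df)
        assert list(out["mouse_id"]) == ["a"]
        assert out.loc[0, "firing_hz"] == 2.0
        out_all = per_mouse_mean(df, require_putative_da=False)
        assert len(out_all) == 2


class TestGroupEffectRecovery:
    def test_stressed_firing_depression_recovered(self, small_cohort_cfg):
        """Extracted per-mouse firing is lower in stressed mice, tracking
        the programmed trait-driven depression."""
        _, gt = gen_cohort(small_cohort_cfg)
        t = gt.table
        seeds = mouse_seeds(small_cohort_cfg.seed, len(t), "ephys-test")
        rates = []
        for i, row in t.reset_index(drop=True).iterrows():
            trace, _, fs = gen_cell_attached(row.firing_hz, 60.0, seed=seeds[i])
            rates.append(firing_rate(detect_spikes(trace, fs), 60.0))
        t = t.assign(rate=rates)
        rec = t.loc[~t.stressed, "rate"].mean() - t.loc[t.stressed, "rate"].mean()
        prog = gt.programmed_firing_depression_hz
        assert rec > 0
        # single-neuron estimate per mouse: counting noise ~sqrt(rate/60)
        assert rec == pytest.approx(prog, abs=0.6)

    def test_firing_rate_bias_below_three_percent(self):
        """At 60 s records the extracted rate is nearly unbiased."""
        est, true = [], []
        for seed in range(8):
            trace, truth, fs = gen_cell_attached(4.0, 60.0, seed=seed + 50)
            est.append(firing_rate(detect_spikes(trace, fs), 60.0))
            true.append(len(truth) / 60.0)
        bias = abs(np.mean(est) - np.mean(true)) / np.mean(true)
        assert bias < 0.03
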