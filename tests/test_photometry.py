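"""Photometry processing chain: fit, dF/F, AUC, events, peri-event."""

import numpy as np
import pytest

from csdsphys.core import PhotometryRecording
from csdsphys.photometry import (
    DffSeries,
    compartment_auc,
    detect_events,
    dff,
    fit_control,
    peri_event,
    sliding_slope,
    summary_bin,
)

FS = 381.0


def make_rec(f490, f405, rate=FS):
    n = len(f490)
    return PhotometryRecording(np.arange(n) / rate, np.asarray(f490, float),
                               np.asarray(f405, float), rate)


def make_series(values, rate=FS):
    v = np.asarray(values, dtype=float)
    z = (v - v.mean()) / v.std() if v.std() > 0 else np.zeros_like(v)
    return DffSeries(np.arange(len(v)) / rate, v, z, np.nan, np.nan, rate)


class TestFitControl:
    def test_identity_channels(self):
        rng = np.random.default_rng(0)
        x = 50 + rng.random(1000)
        s, i, fitted = fit_control(make_rec(x, x))
        assert s == pytest.approx(1.0, abs=1e-9)
        assert i == pytest.approx(0.0, abs=1e-6)

    def test_exact_affine_relation(self):
        rng = np.random.default_rng(1)
        x = 50 + rng.random(1000)
        s, i, _ = fit_control(make_rec(2 * x + 3, x))
        assert s == pytest.approx(2.0, abs=1e-9)
        assert i == pytest.approx(3.0, abs=1e-6)

    def test_noisy_recovery_matches_closed_form_ols(self):
        rng = np.random.default_rng(2)
        x = 60 + rng.normal(0, 2, 5000)
        y = 1.7 * x + 4.0 + rng.normal(0, 0.5, 5000)
        s, i, _ = fit_control(make_rec(y, x))
        # independent normal-equation oracle
        sxx = np.sum((x - x.mean()) ** 2)
        slope_oracle = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        inter_oracle = y.mean() - slope_oracle * x.mean()
        assert s == pytest.approx(slope_oracle, rel=1e-12)
        assert i == pytest.approx(inter_oracle, rel=1e-9)
        # and recovery sits inside the OLS standard-error band
        resid = y - (s * x + i)
        se = np.sqrt(resid.var(ddof=2) / sxx)
        assert abs(s - 1.7) < 4 * se

    def test_constant_control_falls_back_with_warning(self, caplog):
        s, i, fitted = fit_control(make_rec([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]))
        assert s == 0.0
        assert i == pytest.approx(2.0)


class TestDff:
    def test_equal_channels_give_zero(self):
        rng = np.random.default_rng(3)
        x = 50 + rng.random(1000)
        series = dff(make_rec(x, x))
        assert np.allclose(series.dff, 0.0, atol=1e-9)

    def test_ten_percent_excursion(self):
        fitted = np.full(1000, 80.0)
        f490 = fitted.copy()
        f490[500] *= 1.10
        rec = make_rec(f490, fitted)
        series = dff(rec, fitted405=fitted, slope=1.0, intercept=0.0)
        assert series.dff[500] == pytest.approx(0.10)
        assert series.dff[499] == pytest.approx(0.0)

    def test_nonpositive_fit_names_offending_sample(self):
        fitted = np.full(500, 10.0)
        fitted[42] = -1.0
        with pytest.raises(ValueError, match="42"):
            dff(make_rec(np.ones(500), np.ones(500)), fitted405=fitted)

    def test_session_zscore_is_normalized_and_idempotent(self):
        rng = np.random.default_rng(4)
        series = dff(make_rec(50 + rng.random(4000), 40 + rng.random(4000)))
        assert abs(series.z.mean()) < 1e-9
        assert series.z.std() == pytest.approx(1.0, abs=1e-9)
        z2 = (series.z - series.z.mean()) / series.z.std()
        assert np.allclose(z2, series.z, atol=1e-9)

    def test_common_gain_cancels(self):
        rng = np.random.default_rng(5)
        f405 = 60 + rng.normal(0, 2, 3000)
        f490 = 1.5 * f405 + 5 + rng.normal(0, 0.3, 3000)
        a = dff(make_rec(f490, f405))
        b = dff(make_rec(7.3 * f490, 7.3 * f405))
        assert np.allclose(a.dff, b.dff, atol=1e-9)


class TestCompartmentAuc:
    def test_rectangle(self):
        n = int(10 * FS) + 1
        series = make_series(np.zeros(n))
        series.z = np.ones(n)
        mask = np.ones(n, dtype=bool)
        res = compartment_auc(series, {"zone": mask})["zone"]
        assert res.auc == pytest.approx(10.0, rel=1e-6)
        assert res.auc_per_s == pytest.approx(1.0, rel=1e-6)

    def test_triangle(self):
        n = int(10 * FS) + 1
        series = make_series(np.zeros(n))
        series.z = np.linspace(0, 1, n)
        res = compartment_auc(series, {"zone": np.ones(n, bool)})["zone"]
        assert res.auc == pytest.approx(5.0, rel=1e-6)

    def test_matches_brute_force_over_random_mask(self):
        rng = np.random.default_rng(6)
        n = 4000
        series = make_series(rng.normal(size=n))
        mask = rng.random(n) < 0.4
        res = compartment_auc(series, {"zone": mask})["zone"]
        # brute force: trapezoid over every maximal run of True
        dt = 1.0 / FS
        total = 0.0
        i = 0
        while i < n:
            if mask[i]:
                j = i
                while j < n and mask[j]:
                    j += 1
                if j - i >= 2:
                    total += np.trapezoid(series.z[i:j], dx=dt)
                i = j
            else:
                i += 1
        assert res.auc == pytest.approx(total, rel=1e-9)

    def test_additive_over_visits(self):
        rng = np.random.default_rng(7)
        n = 3000
        series = make_series(rng.normal(size=n))
        m1 = np.zeros(n, bool); m1[100:600] = True
        m2 = np.zeros(n, bool); m2[1500:2200] = True
        both = m1 | m2
        a = compartment_auc(series, {"z": m1})["z"].auc
        b = compartment_auc(series, {"z": m2})["z"].auc
        c = compartment_auc(series, {"z": both})["z"].auc
        assert c == pytest.approx(a + b, rel=1e-9)

    def test_empty_mask_flags_zero_duration(self):
        series = make_series(np.zeros(500))
        res = compartment_auc(series, {"z": np.zeros(500, bool)})["z"]
        assert res.auc == 0.0 and res.zero_duration


class TestDetectEvents:
    def test_constant_signal_yields_no_events(self):
        series = make_series(np.full(2000, 3.3))
        ev = detect_events(series)
        assert len(ev.times_s) == 0 and ev.degenerate

    def test_gaussian_threshold_crosses_at_expected_tail(self):
        """median + 2.91 x raw MAD sits at ~1.96 sd: a ~2.5% upper tail."""
        rng = np.random.default_rng(8)
        d = rng.standard_normal(1_000_000)
        series = make_series(d)
        ev = detect_events(series)
        frac_above = np.mean(d > ev.threshold)
        assert frac_above == pytest.approx(0.025, abs=0.003)

    def test_single_transient_detected_at_peak(self):
        n = int(60 * FS)
        d = np.zeros(n)
        t = np.arange(n) / FS
        onset = 30.0
        k = (t >= onset) * (1 - np.exp(-(t - onset) / 0.18)) * np.exp(-(t - onset) / 1.4)
        series = make_series(d + np.clip(k, 0, None))
        ev = detect_events(series)
        assert len(ev.times_s) == 1
        true_peak = onset + 0.18 * np.log1p(1.4 / 0.18)
        assert abs(ev.times_s[0] - true_peak) <= 0.05

    def test_event_count_monotone_in_transient_amplitude(self):
        """Counting transient-attributable events: with the noise floor
        fixed at zero the count is non-decreasing in injected amplitude
        (with Gaussian noise the MAD threshold self-calibrates, so the
        noise-crossing count is amplitude-invariant by construction and
        the sweep is only meaningful on the transient component)."""
        n = int(120 * FS)
        t = np.arange(n) / FS
        onsets = np.arange(5, 115, 5.0)
        kernel = np.zeros(n)
        for onset in onsets:
            m = t >= onset
            kernel[m] += (1 - np.exp(-(t[m] - onset) / 0.18)) * np.exp(-(t[m] - onset) / 1.4)
        counts = []
        for amp in (0.0, 0.01, 0.03, 0.1):
            ev = detect_events(make_series(amp * kernel), min_interval_s=1.0)
            counts.append(len(ev.times_s))
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert counts[0] == 0
        assert counts[-1] >= len(onsets) * 0.8

    def test_short_record_rejected(self):
        with pytest.raises(ValueError):
            detect_events(make_series(np.zeros(100)))

    def test_events_per_min_definition(self):
        rng = np.random.default_rng(10)
        series = make_series(rng.standard_normal(int(120 * FS)))
        ev = detect_events(series)
        assert ev.events_per_min == pytest.approx(len(ev.times_s) / 2.0)


class TestPeriEvent:
    def test_white_noise_summary_near_zero(self):
        rng = np.random.default_rng(11)
        series = make_series(rng.standard_normal(int(300 * FS)))
        onsets = [(float(t), "go") for t in np.arange(10, 290, 10.0)]
        pe = peri_event(series, onsets, mouse_id="m1", max_epochs_per_mouse=100)["go"]
        assert abs(pe.summary_z) < 0.5

    def test_epoch_baseline_mean_is_exactly_offset(self):
        rng = np.random.default_rng(12)
        series = make_series(rng.standard_normal(int(100 * FS)))
        pe = peri_event(series, [(20.0, "a"), (50.0, "a")], mouse_id="m")["a"]
        base = (pe.time_s >= -5.0) & (pe.time_s <= -4.0)
        for epoch in pe.epochs:
            assert abs(epoch[base].mean()) < 1e-9

    def test_step_response_matches_hand_computed_window_transform(self):
        """A deterministic step of height h at the onset: the plateau of
        the averaged trace equals the window z-transform of the step
        computed by hand on one window."""
        n = int(60 * FS)
        d = np.zeros(n)
        onset = 30.0
        h = 2.0
        d[int(onset * FS):] = h
        series = make_series(d)
        pe = peri_event(series, [(onset, "s")], mouse_id="m")["s"]

        # hand computation on the raw window
        i0 = int(np.floor(onset * FS + 0.5))
        n_half = int(round(5 * FS))
        w = d[i0 - n_half: i0 + n_half + 1]
        wz = (w - w.mean()) / w.std()
        tgrid = np.arange(-n_half, n_half + 1) / FS
        wz = wz - wz[(tgrid >= -5) & (tgrid <= -4)].mean()
        assert np.allclose(pe.epochs[0], wz, atol=1e-9)
        assert pe.mean_trace[-1] == pytest.approx(wz[-1])

    def test_epoch_cap_per_mouse(self):
        rng = np.random.default_rng(13)
        series = make_series(rng.standard_normal(int(200 * FS)))
        onsets = [(float(t), "x") for t in np.arange(10, 150, 20.0)]  # 7 onsets
        pe = peri_event(series, onsets, mouse_id="m")["x"]
        assert pe.epochs.shape[0] == 5

    def test_edge_onsets_skipped(self):
        rng = np.random.default_rng(14)
        series = make_series(rng.standard_normal(int(30 * FS)))
        pe = peri_event(series, [(2.0, "e"), (15.0, "e"), (28.0, "e")], mouse_id="m")["e"]
        assert pe.epochs.shape[0] == 1


class TestSlopesAndSummary:
    def test_linear_trace_recovers_slope(self):
        t = np.arange(0, 10, 1 / FS)
        times, slopes = sliding_slope(t - 5.0, 3.5 * t)
        assert np.allclose(slopes, 3.5, atol=1e-6)

    def test_constant_trace_zero_slope(self):
        t = np.arange(0, 10, 1 / FS)
        _, slopes = sliding_slope(t, np.full_like(t, 2.0))
        assert np.allclose(slopes, 0.0, atol=1e-9)

    def test_quadratic_trace_matches_derivative_to_window_order(self):
        t = np.arange(-5, 5, 1 / FS)
        times, slopes = sliding_slope(t, t**2, window_s=0.5)
        assert np.allclose(slopes, 2 * times, atol=1e-6)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            sliding_slope(np.arange(10) / FS, np.zeros(10), window_s=0.5)

    @pytest.mark.parametrize("trace_fn,want", [
        (lambda t: np.full_like(t, 4.2), 4.2),
        (lambda t: t, 0.0),            # odd ramp averages out
        (lambda t: np.sin(2 * np.pi * t), 0.0),
    ])
    def test_summary_bin_symmetries(self, trace_fn, want):
        t = np.arange(-5, 5 + 1 / FS, 1 / FS)
        assert summary_bin(t, trace_fn(t)) == pytest.approx(want, abs=1e-2)

    def test_summary_bin_requires_coverage(self):
        with pytest.raises(ValueError):
            summary_bin(np.array([2.0, 3.0]), np.array([1.0, 1.0]))
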