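"""Optical AP analysis: extraction, drift, detection, metrics, shapes."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panomap import (
    ExtractionMask,
    FiberTrace,
    FrameStack,
    MetricsError,
    ShapeClass,
    TraceError,
    analyze_trace,
    compute_ap_metrics,
    correct_drift,
    detect_aps,
    extract_traces,
)
from conftest import logistic, make_ap_trace


FS = 10000.0
DT = 0.1


class TestExtractTraces:
    def test_uniform_frames_constant_trace_both_filters(self):
        frames = np.full((20, 10, 10), 7.0)
        for filt in ("mean", "gaussian"):
            stack = FrameStack(frames, FS)
            mask = ExtractionMask({0: (0, 0), 1: (0, 5)}, spatial_filter=filt)
            traces = extract_traces(stack, mask)
            for tr in traces:
                assert np.allclose(tr.samples, 7.0)

    def test_mean_filter_of_central_block(self):
        frames = np.zeros((3, 5, 5))
        frames[:, 1:4, 1:4] = np.arange(1, 10).reshape(3, 3)
        traces = extract_traces(FrameStack(frames, FS), ExtractionMask({0: (0, 0)}))
        assert np.allclose(traces[0].samples, 5.0)

    def test_gaussian_filter_center_weight(self):
        frames = np.zeros((2, 5, 5))
        frames[:, 2, 2] = 10.0  # single bright pixel at the block center
        tr = extract_traces(
            FrameStack(frames, FS), ExtractionMask({0: (0, 0)}, spatial_filter="gaussian")
        )[0]
        from panomap.optical import _gaussian_core_weights

        w = _gaussian_core_weights()
        assert np.allclose(tr.samples, w[1, 1] * 10.0)

    def test_out_of_bounds_and_overlap_rejected(self):
        frames = np.zeros((2, 8, 8))
        with pytest.raises(TraceError):
            extract_traces(FrameStack(frames, FS), ExtractionMask({0: (5, 5)}))
        with pytest.raises(TraceError):
            ExtractionMask({0: (0, 0), 1: (2, 2)})


class TestCorrectDrift:
    def test_drift_free_trace_unchanged(self):
        tr = make_ap_trace(noise_sd=0.0)
        out = correct_drift(tr, 3, ap_mask=[(400, 1100)])
        assert np.allclose(out.samples, tr.samples, atol=1e-9)

    def test_known_linear_ramp_removed(self):
        tr = make_ap_trace(noise_sd=0.0)
        slope = 0.05  # units per ms
        ramped = FiberTrace(0, tr.samples + slope * tr.times_ms, FS)
        out = correct_drift(ramped, 1, ap_mask=[(400, 1350)])
        # recovered template shape (DC-free) deviates < 1e-6 of APA; the
        # preserved offset is the mean baseline level by construction
        assert np.max(np.abs((out.samples - out.baseline_F) - (tr.samples - 500.0))) < 1e-6 * 100.0

    def test_constant_trace_any_order(self):
        tr = FiberTrace(0, np.full(1000, 42.0), FS)
        for order in (0, 2, 4):
            assert np.allclose(correct_drift(tr, order).samples, 42.0)

    def test_insufficient_baseline_rejected(self):
        tr = FiberTrace(0, np.arange(100.0), FS)
        with pytest.raises(TraceError):
            correct_drift(tr, 3, ap_mask=[(0, 97)])


class TestDetectAps:
    def test_flat_noise_yields_nothing(self):
        rng = np.random.default_rng(0)
        tr = FiberTrace(0, 100 + rng.normal(0, 1, 3000), FS)
        assert detect_aps(tr) == []

    def test_train_detected_at_correct_onsets(self):
        lats = np.arange(60, 1500, 150.0)
        t = np.arange(0, 1600, DT)
        sig = sum(logistic(t, L, 6) * (1 - logistic(t, L + 40, 0.25)) for L in lats)
        rng = np.random.default_rng(1)
        tr = FiberTrace(0, 100 + 10 * sig + rng.normal(0, 0.5, len(t)), FS)  # SNR 20
        ivs = detect_aps(tr)
        assert len(ivs) == len(lats)
        for iv, L in zip(ivs, lats):
            assert abs(iv.onset * DT - L) <= 2.0

    def test_close_aps_flagged_not_merged(self):
        t = np.arange(0, 300, DT)
        sig = logistic(t, 100, 6) * (1 - logistic(t, 140, 0.5)) + logistic(t, 115, 6) * (
            1 - logistic(t, 155, 0.5)
        )
        rng = np.random.default_rng(2)
        tr = FiberTrace(0, 100 + 10 * sig + rng.normal(0, 0.05, len(t)), FS)
        ivs = detect_aps(tr)
        assert len(ivs) == 2
        assert all("close_spacing" in iv.flags for iv in ivs)

    def test_window_longer_than_trace_rejected(self):
        tr = FiberTrace(0, np.zeros(9), FS)
        with pytest.raises(TraceError):
            detect_aps(tr, sg_window=11)


class TestApMetrics:
    def test_linear_upstroke_closed_form(self):
        t = np.arange(0, 150, DT)
        y = np.zeros_like(t)
        up = (t >= 50) & (t < 60)
        y[up] = (t[up] - 50) * 10  # 0 -> 100% over 10 ms
        y[(t >= 60) & (t < 100)] = 100
        y[t >= 100] = np.maximum(100 - (t[t >= 100] - 100) * 20, 0)
        rng = np.random.default_rng(0)
        tr = FiberTrace(0, 1000 + y + rng.normal(0, 1e-6, len(t)), FS)
        m = compute_ap_metrics(tr, detect_aps(tr)[0])
        assert m.dVdt_max == pytest.approx(10.0, rel=0.01)
        assert m.olat_50 == pytest.approx(55.0, abs=0.05)
        assert m.dFF_percent == pytest.approx(10.0, rel=0.005)

    def test_logistic_upstroke_analytic_peak(self):
        # d/dt of 100/(1+e^(-k t)) peaks at 25 k %APA/ms at the midpoint
        k = 1.0
        t = np.arange(0, 200, DT)
        y = 100 * logistic(t, 80, k)
        y[t > 150] *= np.exp(-(t[t > 150] - 150) / 10)
        rng = np.random.default_rng(1)
        tr = FiberTrace(0, 500 + y + rng.normal(0, 1e-6, len(t)), FS)
        m = compute_ap_metrics(tr, detect_aps(tr)[0])
        assert m.dVdt_max == pytest.approx(25.0 * k, rel=0.02)
        # symmetric upstroke: the two oLAT definitions coincide
        assert abs(m.olat_sg - m.olat_50) <= DT
        assert m.olat_50 == pytest.approx(80.0, abs=DT)

    def test_square_ap_duration_all_levels(self):
        t = np.arange(0, 150, DT)
        y = np.where((t >= 50) & (t < 80), 50.0, 0.0)
        rng = np.random.default_rng(2)
        tr = FiberTrace(0, 200 + y + rng.normal(0, 1e-6, len(t)), FS)
        m = compute_ap_metrics(tr, detect_aps(tr)[0])
        for level, apd in m.apd.items():
            assert apd == pytest.approx(30.0, abs=0.5)

    def test_snr_formula_and_zero_rest_sd(self):
        tr = make_ap_trace(amplitude=10.0, noise_sd=0.5, seed=3)
        m = compute_ap_metrics(tr, detect_aps(tr)[0])
        assert m.snr == pytest.approx(20.0, rel=0.25)
        clean = make_ap_trace(amplitude=10.0, noise_sd=0.0)
        with pytest.raises(MetricsError):
            compute_ap_metrics(clean, detect_aps(clean)[0])

    def test_saturation_excluded_with_reason(self):
        tr = make_ap_trace(noise_sd=0.01, seed=4)
        sat = FiberTrace(0, np.minimum(tr.samples, 590.0), FS, saturation_value=590.0)
        m = compute_ap_metrics(sat, detect_aps(sat)[0])
        assert m.excluded and m.exclusion_reason == "saturation"

    def test_apd_monotone_across_noise(self):
        for seed in range(10):
            tr = make_ap_trace(noise_sd=0.7, seed=seed, amplitude=15.0)
            ms = [m for m in analyze_trace(tr) if not m.excluded]
            for m in ms:
                levels = sorted(m.apd)
                vals = [m.apd[l] for l in levels if np.isfinite(m.apd[l])]
                assert vals == sorted(vals)

    def test_pipeline_determinism(self):
        tr = make_ap_trace(noise_sd=0.5, seed=11)
        a = analyze_trace(tr)
        b = analyze_trace(tr)
        assert [m.olat_50 for m in a] == [m.olat_50 for m in b]
        assert [m.dFF_percent for m in a] == [m.dFF_percent for m in b]

    def test_first_order_filtered_step_shifts_by_tau_ln2(self):
        # analytic limit: a step through a first-order filter crosses 50%
        # tau*ln2 after the step time
        from panomap import first_order_filter

        t = np.arange(0, 100, DT)
        step = (t >= 40).astype(float)
        for tau in (1.0, 3.5):
            filt = first_order_filter(step, DT, tau, tau)
            rng = np.random.default_rng(5)
            tr = FiberTrace(0, 300 + 20 * filt + rng.normal(0, 1e-7, len(t)), FS)
            m = compute_ap_metrics(tr, detect_aps(tr)[0])
            assert m.olat_50 == pytest.approx(40 + tau * np.log(2), abs=DT)


class TestShapeClassification:
    def _metrics(self, samples, fs=FS):
        rng = np.random.default_rng(0)
        tr = FiberTrace(0, samples + rng.normal(0, 0.03, len(samples)), fs)
        ivs = detect_aps(tr)
        assert ivs, "fixture produced no detection"
        return compute_ap_metrics(tr, ivs[0])

    def test_single_logistic_is_shape2(self):
        t = np.arange(0, 300, DT)
        self_m = self._metrics(300 + 100 * logistic(t, 50, 2))
        assert self_m.shape_class is ShapeClass.SHAPE2

    def test_foot_then_fast_rise_is_shape1(self):
        t = np.arange(0, 300, DT)
        foot = np.clip(15 * (1 - np.exp(-np.clip(t - 40, 0, None) / 5)), 0, None) * (t < 60)
        main = (15 + 85 * logistic(t, 61, 6)) * (t >= 60)
        m = self._metrics(300 + np.where(t < 60, foot, main))
        assert m.shape_class is ShapeClass.SHAPE1

    def test_two_phase_rise_is_shape3(self):
        t = np.arange(0, 300, DT)
        u = 60 * logistic(t, 50, 6) + 40 * logistic(t, 54, 1.2)
        m = self._metrics(300 + u)
        assert m.shape_class is ShapeClass.SHAPE3

    def test_coarse_sampling_unclassified(self):
        # at 250 Hz a 1-2 sample upstroke cannot be shape-classified
        t = np.arange(0, 400, 4.0)
        u = 100 * logistic(t, 200, 2.5)
        rng = np.random.default_rng(1)
        tr = FiberTrace(0, 300 + u + rng.normal(0, 0.05, len(t)), 250.0)
        m = compute_ap_metrics(tr, detect_aps(tr, sg_window=5)[0], sg_window=5)
        assert m.shape_class is ShapeClass.UNCLASSIFIED


@settings(deadline=None, max_examples=20, derandomize=True)
@given(
    lat=st.floats(min_value=60.0, max_value=90.0),
    amplitude=st.floats(min_value=5.0, max_value=50.0),
    baseline=st.floats(min_value=100.0, max_value=2000.0),
)
def test_metrics_scale_invariances(lat, amplitude, baseline):
    """dF/F tracks amplitude/baseline; oLAT_50 tracks the true midpoint."""
    tr = make_ap_trace(lat_ms=lat, amplitude=amplitude, baseline=baseline,
                       noise_sd=amplitude * 1e-6, seed=9)
    m = compute_ap_metrics(tr, detect_aps(tr)[0])
    assert m.dFF_percent == pytest.approx(100 * amplitude / baseline, rel=0.01)
    assert m.olat_50 == pytest.approx(lat, abs=0.2)
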