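"""Sigma estimation, 3-sigma detection, and five-feature extraction."""

import numpy as np
import pytest

from porepulse import (
    BaselineModel,
    CurrentTrace,
    DetectionConfig,
    detect_events,
    estimate_sigma,
    extract_features,
)

RATE = 100_000.0


def _trapezoid(depth, total, edge):
    """Deviation profile of one trapezoidal blockade (in samples)."""
    prof = np.full(total, depth, dtype=float)
    ramp = np.linspace(0, depth, edge, endpoint=False)
    prof[:edge] = ramp
    prof[-edge:] = ramp[::-1]
    return prof


class TestEstimateSigma:
    def test_constant_series_gives_zero(self):
        assert estimate_sigma(np.full(1000, 3.3)) == 0.0
        assert estimate_sigma(np.full(1000, 3.3), "global_sd") == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_noise_recovered_within_two_percent(self):
        x = np.random.default_rng(0).normal(0, 1.0, 100_000)
        assert estimate_sigma(x, "robust_mad") == pytest.approx(1.0, rel=0.02)

    def test_robust_to_event_contamination(self):
        # 5% of samples pushed to +10 sigma: the MAD estimate stays near the
        # noise sd while the plain sd is inflated by more than 50%.
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1.0, 100_000)
        idx = rng.choice(x.size, x.size // 20, replace=False)
        x[idx] = 10.0
        assert estimate_sigma(x, "robust_mad") == pytest.approx(1.0, rel=0.10)
        assert estimate_sigma(x, "global_sd") > 1.5

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            estimate_sigma(np.ones(50))


class TestDetectEvents:
    CFG = DetectionConfig()

    def test_flat_deviation_gives_no_events(self):
        out = detect_events(np.zeros(10_000), self.CFG, sigma=1.0, sampling_rate=RATE)
        assert out == []

    def test_ten_injected_trapezoids_all_found(self):
        dev = np.zeros(60_000)
        onsets = 2000 + 5000 * np.arange(10)
        for s in onsets:
            dev[s : s + 100] = _trapezoid(6.0, 100, 25)
        found = detect_events(dev, self.CFG, sigma=1.0, sampling_rate=RATE)
        assert len(found) == 10
        for (start, peak, end), s in zip(found, onsets):
            # Boundaries sit at the 1-sigma crossings on the flanks, a few
            # samples inside the injected onset/offset.
            assert s <= start <= s + 10 and s + 90 <= end <= s + 100
            assert start < peak < end

    def test_subthreshold_event_not_detected(self):
        dev = np.zeros(10_000)
        dev[5000:5100] = _trapezoid(2.0, 100, 25)
        assert detect_events(dev, self.CFG, sigma=1.0, sampling_rate=RATE) == []

    def test_events_sorted_and_disjoint(self, benchmark_table):
        for _, sub in benchmark_table.groupby("label"):
            starts = sub["start_idx"].to_numpy()
            ends = sub["end_idx"].to_numpy()
            assert np.all(np.diff(starts) > 0)
            assert np.all(starts[1:] >= ends[:-1])

    def test_min_dwell_discards_brief_excursions(self):
        dev = np.zeros(10_000)
        dev[5000:5003] = 6.0  # 3 samples above threshold
        cfg = DetectionConfig(min_dwell_s=5e-5)  # 5 samples at 100 kHz
        assert detect_events(dev, cfg, sigma=1.0, sampling_rate=RATE) == []

    def test_edge_margin_discards_boundary_events(self):
        dev = np.zeros(10_000)
        dev[100:200] = 6.0
        out = detect_events(dev, self.CFG, sigma=1.0, sampling_rate=RATE, edge_margin=500)
        assert out == []


def _make_triangle(m=500, a=1e-9, i0=1e-8):
    """Triangular event: rises linearly over m samples, falls over m."""
    dev = np.zeros(2 * m + 1)
    dev[: m + 1] = a * np.arange(m + 1) / m
    dev[m:] = a * (1 - np.arange(m + 1) / m)
    baseline = np.full(dev.size, i0)
    trace = CurrentTrace(baseline - dev, RATE)
    return trace, BaselineModel(baseline=baseline, deviation=dev, edge_margin=0)


class TestExtractFeatures:
    def test_triangle_closed_form(self):
        # depth a over duration d: dI/I0 = a/I0, dt = d, AUC = a d/2,
        # LS = +2a/d, RS = -2a/d.
        m, a, i0 = 500, 1e-9, 1e-8
        trace, model = _make_triangle(m, a, i0)
        rec = extract_features(trace, model, (0, m, 2 * m))
        d = 2 * m / RATE
        assert rec.rel_blockade == pytest.approx(a / i0, rel=1e-12)
        assert rec.dwell_s == pytest.approx(d, rel=1e-12)
        assert rec.auc == pytest.approx(a * d / 2, rel=5e-3)
        assert rec.left_slope == pytest.approx(2 * a / d, rel=1e-9)
        assert rec.right_slope == pytest.approx(-2 * a / d, rel=1e-9)

    def test_symmetric_pulse_has_opposite_slopes(self):
        trace, model = _make_triangle()
        rec = extract_features(trace, model, (0, 500, 1000))
        assert rec.left_slope == pytest.approx(-rec.right_slope, rel=1e-9)

    def test_current_scaling_behaviour(self):
        # Doubling all currents leaves dI/I0 and dt unchanged and doubles
        # AUC and both slopes.
        trace, model = _make_triangle()
        scaled = CurrentTrace(2 * trace.samples, RATE)
        smodel = BaselineModel(
            baseline=2 * model.baseline, deviation=2 * model.deviation, edge_margin=0
        )
        r1 = extract_features(trace, model, (0, 500, 1000))
        r2 = extract_features(scaled, smodel, (0, 500, 1000))
        assert r2.rel_blockade == pytest.approx(r1.rel_blockade, rel=1e-12)
        assert r2.dwell_s == r1.dwell_s
        assert r2.auc == pytest.approx(2 * r1.auc, rel=1e-12)
        assert r2.left_slope == pytest.approx(2 * r1.left_slope, rel=1e-9)
        assert r2.right_slope == pytest.approx(2 * r1.right_slope, rel=1e-9)

    def test_peak_at_boundary_discarded(self):
        trace, model = _make_triangle()
        assert extract_features(trace, model, (500, 500, 1000)) is None


class TestBenchmarkRecovery:
    """Detection and feature fidelity on the simulated benchmark."""

    def test_all_detected_dwells_exceed_min_dwell(self, benchmark_table):
        assert (benchmark_table["dwell_s"] >= 3e-4).all()

    def test_slopes_have_expected_signs(self, benchmark_table):
        assert (benchmark_table["left_slope"] > 0).all()
        assert (benchmark_table["right_slope"] < 0).all()

    def test_detection_recall_on_benchmark(self, benchmark_matched):
        _, recall = benchmark_matched
        assert recall >= 0.95
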