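"""Synthetic trace generator: determinism, event placement, rendering."""

import numpy as np
import pandas as pd
import pytest

from porepulse import (
    CapacityError,
    ClassModel,
    EventSpec,
    SimulationConfig,
    make_benchmark_dataset,
    render_trace,
    sample_events,
)
from porepulse.stats import density_histogram

MODEL = ClassModel("x", 0.085, 0.02, 1.0e-3, 1.7, asymmetry_mean=0.0)


class TestSampleEvents:
    def test_zero_events_gives_empty_list(self):
        assert sample_events(MODEL, 0, 1, trace_duration=1.0) == []

    def test_same_seed_gives_identical_lists(self):
        a = sample_events(MODEL, 50, 123, trace_duration=5.0)
        b = sample_events(MODEL, 50, 123, trace_duration=5.0)
        assert a == b

    def test_events_separated_by_smoothing_window(self):
        events = sample_events(MODEL, 40, 5, trace_duration=4.0)
        onsets = np.array([e.onset for e in events])
        ends = onsets + np.array([e.dwell for e in events])
        assert np.all(onsets[1:] - ends[:-1] >= 4801 / 100_000.0 - 1e-12)

    def test_sample_median_dwell_near_model_median(self):
        # Un-truncated model: the sample median estimates the model median.
        model = ClassModel("x", 0.085, 0.02, 1.0e-3, 1.7, dwell_min_s=0.0)
        events = sample_events(model, 200, 42, trace_duration=25.0)
        med = np.median([e.dwell for e in events])
        assert med == pytest.approx(1.0e-3, rel=0.15)

    def test_capacity_error_when_trace_too_short(self):
        with pytest.raises(CapacityError):
            sample_events(MODEL, 100, 1, trace_duration=1.0)

    def test_event_invariants_hold(self):
        for e in sample_events(MODEL, 100, 9, trace_duration=9.0):
            assert 0 < e.rel_amplitude < 1
            assert e.dwell > 0
            assert e.rise_fraction + e.fall_fraction <= 1


class TestRenderTrace:
    def test_clean_config_gives_constant_baseline(self):
        cfg = SimulationConfig(
            duration=0.01, noise_sigma=0.0, drift_amplitude=0.0, drift_rw_step=0.0
        )
        trace, truth = render_trace(cfg, [])
        assert np.allclose(trace.samples, cfg.i0)
        assert truth.empty

    def test_single_event_depth(self):
        cfg = SimulationConfig(
            duration=0.05,
            baseline_current=1e-8,
            noise_sigma=0.0,
            drift_amplitude=0.0,
            drift_rw_step=0.0,
        )
        ev = EventSpec(onset=0.02, rel_amplitude=0.1, dwell=2e-3,
                       rise_fraction=0.25, fall_fraction=0.25)
        trace, truth = render_trace(cfg, [ev])
        assert trace.samples.min() == pytest.approx(9e-9, rel=1e-9)
        assert len(truth) == 1

    def test_event_free_mean_near_baseline(self):
        cfg = SimulationConfig(
            duration=0.5, noise_sigma=1.5e-12, drift_amplitude=0.0, drift_rw_step=0.0,
            seed=4,
        )
        trace, _ = render_trace(cfg, [])
        n = trace.n
        assert abs(trace.samples.mean() - cfg.i0) < 3 * cfg.noise_sigma / np.sqrt(n)

    def test_event_free_noise_sd_matches_config(self):
        cfg = SimulationConfig(
            duration=1.2, noise_sigma=1.5e-12, drift_amplitude=0.0, drift_rw_step=0.0,
            seed=5,
        )
        trace, _ = render_trace(cfg, [])
        assert trace.n >= 100_000
        assert trace.samples.std() == pytest.approx(cfg.noise_sigma, rel=0.1)

    def test_overlapping_events_rejected(self):
        cfg = SimulationConfig(duration=0.05, noise_sigma=0.0)
        e1 = EventSpec(0.01, 0.1, 2e-3, 0.2, 0.2)
        e2 = EventSpec(0.011, 0.1, 2e-3, 0.2, 0.2)
        with pytest.raises(ValueError, match="overlap"):
            render_trace(cfg, [e1, e2])

    def test_bit_reproducible_under_fixed_seed(self):
        cfg = SimulationConfig(duration=0.2, seed=11)
        events = sample_events(MODEL, 1, 11, trace_duration=0.2)
        a, _ = render_trace(cfg, events)
        b, _ = render_trace(cfg, events)
        assert np.array_equal(a.samples, b.samples)


class TestBenchmarkDataset:
    def test_empty_dataset_has_valid_schema(self):
        ds = make_benchmark_dataset(n_per_class=0, seed=1)
        assert set(ds.truth.columns) >= {"label", "onset_s", "dwell_s", "rel_amplitude"}
        assert len(ds.truth) == 0

    def test_ground_truth_rows_match_event_count(self, benchmark_dataset):
        counts = benchmark_dataset.truth["label"].value_counts()
        assert set(counts) == {150}
        assert len(counts) == 3

    def test_reproducible_across_calls(self):
        a = make_benchmark_dataset(n_per_class=3, seed=2)
        b = make_benchmark_dataset(n_per_class=3, seed=2)
        for lab in a.traces:
            assert np.array_equal(a.traces[lab].samples, b.traces[lab].samples)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_fewer_than_two_classes_rejected(self):
        with pytest.raises(ValueError):
            make_benchmark_dataset(models=(MODEL,), n_per_class=1)

    def test_blockade_marginals_overlap_heavily(self, benchmark_dataset):
        # Pairwise intersection of normalized densities > 0.5: the classes
        # cannot be told apart from the relative blockade alone.
        truth = benchmark_dataset.truth
        labs = truth["label"].unique()
        hi = truth["rel_amplitude"].max()
        w = 0.01
        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                da = density_histogram(
                    truth.loc[truth.label == labs[i], "rel_amplitude"].to_numpy(),
                    w, (0, hi),
                ).density
                db = density_histogram(
                    truth.loc[truth.label == labs[j], "rel_amplitude"].to_numpy(),
                    w, (0, hi),
                ).density
                assert np.minimum(da, db).sum() * w > 0.5
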