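"""Symbol inventory, trace geometry, and the planted forward model."""

import numpy as np
import pytest

from kfgep.preprocessing import detect_onset, window_rms
from kfgep.synthetic import (
    DIGIT_IDS,
    SHAPE_IDS,
    SYMBOL_IDS,
    SymbolSpec,
    Trial,
    default_forward_model,
    generate_dataset,
    generate_trace,
    linear_forward_model,
    simulate_features,
    simulate_raw_semg,
)


class TestInventory:
    def test_inventory_is_14_shapes_plus_10_digits(self):
        assert len(SHAPE_IDS) == 14
        assert len(DIGIT_IDS) == 10
        assert len(set(SYMBOL_IDS)) == 24

    @pytest.mark.parametrize("symbol", SYMBOL_IDS)
    def test_every_symbol_is_one_bounded_stroke(self, symbol):
        spec = SymbolSpec(symbol_id=symbol, n_points=40, scale=100.0)
        t = generate_trace(spec, rng_seed=5)
        assert t.shape == (40, 2)
        assert np.isfinite(t).all()
        steps = np.linalg.norm(np.diff(t, axis=0), axis=1)
        # single smooth stroke: no teleports relative to the typical step
        assert steps.max() < 8 * np.median(steps) + 1e-9

    def test_unknown_symbol_error_names_the_id(self):
        with pytest.raises(ValueError, match="wiggle"):
            generate_trace(SymbolSpec(symbol_id="wiggle"), 0)


class TestTraceGeometry:
    def test_horizontal_line_is_flat_and_increasing(self):
        spec = SymbolSpec("h_line", n_points=10, scale=100.0, jitter_sd_frac=0.0)
        t = generate_trace(spec, rng_seed=1)
        assert np.allclose(t[:, 1], 0.0, atol=1e-9)
        assert np.all(np.diff(t[:, 0]) > 0)

    def test_reversed_horizontal_line_decreases(self):
        spec = SymbolSpec("rev_h_line", n_points=10, scale=100.0, jitter_sd_frac=0.0)
        t = generate_trace(spec, rng_seed=1)
        assert np.all(np.diff(t[:, 0]) < 0)

    def test_circle_closes_within_one_step(self):
        spec = SymbolSpec("circle", n_points=40, scale=100.0)
        t = generate_trace(spec, rng_seed=2)
        step = np.linalg.norm(np.diff(t, axis=0), axis=1).max()
        assert np.linalg.norm(t[-1] - t[0]) <= step

    def test_starts_exactly_at_start_point(self):
        spec = SymbolSpec("digit_3", n_points=25, start_point=(7.0, -4.0))
        t = generate_trace(spec, rng_seed=3)
        assert np.allclose(t[0], [7.0, -4.0])

    def test_generator_is_pure_function_of_spec_and_seed(self):
        spec = SymbolSpec("triangle", n_points=30)
        assert np.array_equal(generate_trace(spec, 9), generate_trace(spec, 9))
        assert not np.array_equal(generate_trace(spec, 9), generate_trace(spec, 10))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SymbolSpec("circle", n_points=3).validate()
        with pytest.raises(ValueError):
            SymbolSpec("circle", scale=0.0).validate()


class TestForwardModel:
    def test_zero_noise_linear_model_is_exact_map_of_deltas(self, rng):
        fm = linear_forward_model(noise_sd=0.0)
        trace = rng.normal(scale=5, size=(30, 2)).cumsum(axis=0)
        feats = simulate_features(trace, fm, rng_seed=0)
        deltas = np.diff(trace, axis=0)
        expected = deltas @ fm.coef.T + fm.offset
        assert np.array_equal(feats, expected)

    def test_deterministic_given_seed(self, slash_spec):
        t = generate_trace(slash_spec, 4)
        fm = default_forward_model(noise_sd=0.3)
        assert np.array_equal(
            simulate_features(t, fm, 11), simulate_features(t, fm, 11)
        )

    def test_noise_sd_matches_request(self):
        rng = np.random.default_rng(8)
        trace = rng.normal(scale=4, size=(10_001, 2)).cumsum(axis=0)
        fm = default_forward_model(noise_sd=0.1)
        noiseless = fm.evaluate(np.diff(trace, axis=0))
        noisy_unclipped = noiseless + np.random.default_rng(21).normal(
            0, 0.1, noiseless.shape
        )
        feats = simulate_features(trace, fm, rng_seed=21)
        assert np.array_equal(feats, np.clip(noisy_unclipped, 0, None))
        resid = noisy_unclipped - noiseless
        assert np.allclose(resid.std(axis=0), 0.1, rtol=0.05)

    def test_features_are_nonnegative(self, nonlinear_dataset):
        for trial in nonlinear_dataset:
            assert trial.features.min() >= 0.0

    def test_injective_on_velocity_grid(self):
        """Distinct increment vectors map to distinct feature rows."""
        fm = default_forward_model(noise_sd=0.0)
        g = np.linspace(-10, 10, 41)
        dx, dy = np.meshgrid(g, g)
        d = np.column_stack([dx.ravel(), dy.ravel()])
        feats = fm.evaluate(d)
        order = np.lexsort(feats.T)
        f_sorted = feats[order]
        dup = np.all(np.isclose(np.diff(f_sorted, axis=0), 0, atol=1e-9), axis=1)
        assert not dup.any()

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            simulate_features(np.zeros((1, 2)), default_forward_model(), 0)


class TestRawSemg:
    def test_trigger_quiescent_before_onset_and_peaks_at_onset(self, slash_spec):
        t = generate_trace(slash_spec, 6)
        fm = default_forward_model(0.2)
        raw = simulate_raw_semg(t, fm, fs=1000, rng_seed=6, pre_onset_s=0.3)
        pre = int(0.3 * 1000)
        assert np.abs(raw[:pre, 0]).max() < 30.0
        assert detect_onset(raw[:, 0], fs=1000) == pre

    def test_window_rms_matches_target_features(self, slash_spec):
        t = generate_trace(slash_spec, 6)
        fm = default_forward_model(0.2)
        raw = simulate_raw_semg(t, fm, fs=1000, rng_seed=6, pre_onset_s=0.3)
        feats = simulate_features(t, fm, rng_seed=6)
        pre = int(0.3 * 1000)
        for c in range(7):
            rms = window_rms(raw[pre:, 1 + c], fs=1000, window=0.05)
            target = feats[:, c]
            ok = target > 1e-9
            assert np.allclose(rms[ok], target[ok], rtol=0.10)

    def test_window_sample_count_scales_with_fs(self, slash_spec):
        t = generate_trace(slash_spec, 6)
        fm = default_forward_model(0.2)
        raw = simulate_raw_semg(t, fm, fs=2000, rng_seed=1, pre_onset_s=0.1)
        k = t.shape[0] - 1
        assert raw.shape == (int(0.1 * 2000) + k * 100, 8)
        with pytest.raises(ValueError):
            simulate_raw_semg(t, fm, fs=30, rng_seed=1)


class TestDataset:
    def test_shapes_and_alignment(self):
        trials = generate_dataset(
            symbols=("arch", "circle"), trials_per_symbol=3, n_points=12, rng_seed=1
        )
        assert len(trials) == 6
        for tr in trials:
            assert isinstance(tr, Trial)
            assert tr.trace.shape == (12, 2)
            assert tr.features.shape == (11, 7)

    def test_reproducible_and_seed_sensitive(self):
        a = generate_dataset(symbols=("arch",), trials_per_symbol=2, rng_seed=3)
        b = generate_dataset(symbols=("arch",), trials_per_symbol=2, rng_seed=3)
        c = generate_dataset(symbols=("arch",), trials_per_symbol=2, rng_seed=4)
        assert all(np.array_equal(x.trace, y.trace) for x, y in zip(a, b))
        assert not np.array_equal(a[0].trace, c[0].trace)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(trials_per_symbol=0)
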