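"""Training and reconstruction of the fused decoder and its baselines."""

import numpy as np
import pytest

from kfgep.gep import GepConfig
from kfgep.hybrid import (
    KFGEPModel,
    reconstruct,
    reconstruct_gep_only,
    reconstruct_kf_only,
    train,
)
from kfgep.preprocessing import to_deltas
from kfgep.state_model import fit_bilr, fit_linear_observation


@pytest.fixture(scope="module")
def linear_model_and_data():
    """A decoder trained on the noiseless linear world (fast GEP config)."""
    from kfgep.synthetic import generate_dataset, linear_forward_model

    ds = generate_dataset(
        symbols=("fwd_slash", "arch"),
        trials_per_symbol=6,
        n_points=20,
        forward_model=linear_forward_model(noise_sd=0.0),
        rng_seed=11,
    )
    cfg = GepConfig(population_size=60, n_generations=40, rng_seed=5)
    model = train([t.features for t in ds], [t.trace for t in ds], cfg)
    return model, ds


class TestTrain:
    def test_bundle_structure(self, linear_model_and_data):
        model, _ = linear_model_and_data
        assert model.R.shape == (2, 2)
        assert np.allclose(model.R, model.R.T)
        assert np.linalg.eigvalsh(model.R).min() >= -1e-12
        assert model.state_model.A.shape == (2, 2)

    def test_training_is_deterministic_and_serializable(self, linear_dataset):
        cfg = GepConfig(population_size=25, n_generations=6, rng_seed=2)
        feats = [t.features for t in linear_dataset[:4]]
        traces = [t.trace for t in linear_dataset[:4]]
        m1 = train(feats, traces, cfg)
        m2 = train(feats, traces, cfg)
        assert m1.to_json() == m2.to_json()
        clone = KFGEPModel.from_json(m1.to_json())
        assert np.array_equal(clone.observe(feats[0]), m1.observe(feats[0]))

    def test_misaligned_lengths_error_names_both(self, linear_dataset):
        t = linear_dataset[0]
        with pytest.raises(ValueError, match="19"):
            train(t.features[:-2], t.trace)

    def test_single_pair_accepted(self, linear_dataset):
        t = linear_dataset[0]
        cfg = GepConfig(population_size=20, n_generations=4, rng_seed=1)
        model = train(t.features, t.trace, cfg)
        assert model.meta["n_trials"] == 1


class TestReconstruct:
    def test_zero_R_equals_gep_only_path(self, linear_model_and_data):
        model, ds = linear_model_and_data
        forced = KFGEPModel(
            state_model=model.state_model,
            R=np.zeros((2, 2)),
            gep_x=model.gep_x,
            gep_y=model.gep_y,
        )
        t = ds[-1]
        fused = reconstruct(t.features, forced, origin=t.trace[0])
        gep = reconstruct_gep_only(t.features, forced, origin=t.trace[0])
        assert np.allclose(fused, gep, atol=1e-9)

    def test_huge_R_stays_at_pure_prediction_path(self, linear_model_and_data):
        model, ds = linear_model_and_data
        from kfgep.state_model import StateModel

        forced = KFGEPModel(
            state_model=StateModel(A=np.eye(2), Q=np.zeros((2, 2))),
            R=1e12 * np.eye(2),
            gep_x=model.gep_x,
            gep_y=model.gep_y,
        )
        t = ds[-1]
        out = reconstruct(t.features, forced, origin=(0.0, 0.0))
        # S0 = 0 under identity dynamics: pure prediction never leaves origin
        assert np.abs(out).max() < 1e-3

    def test_output_shape_includes_origin(self, linear_model_and_data):
        model, ds = linear_model_and_data
        t = ds[0]
        out = reconstruct(t.features, model, origin=t.trace[0])
        assert out.shape == t.trace.shape
        assert np.allclose(out[0], t.trace[0])

    def test_reconstruction_is_deterministic(self, linear_model_and_data):
        model, ds = linear_model_and_data
        t = ds[2]
        a = reconstruct(t.features, model, origin=t.trace[0])
        b = reconstruct(t.features, model, origin=t.trace[0])
        assert np.array_equal(a, b)

    def test_wrong_feature_width_rejected(self, linear_model_and_data):
        model, _ = linear_model_and_data
        with pytest.raises(ValueError, match="columns"):
            reconstruct(np.zeros((5, 6)), model)


class TestKfOnly:
    def test_linear_world_kf_baseline_is_near_exact(self, linear_dataset):
        cur, nxt, drows, frows = [], [], [], []
        for t in linear_dataset:
            deltas, shifted = to_deltas(t.trace)
            cur.append(deltas[:-1])
            nxt.append(shifted)
            drows.append(deltas)
            frows.append(t.features)
        sm = fit_bilr(np.vstack(cur), np.vstack(nxt))
        H, R = fit_linear_observation(np.vstack(frows), np.vstack(drows))
        t = linear_dataset[0]
        out = reconstruct_kf_only(t.features, sm, H, R, origin=t.trace[0])
        # noiseless linear observations + R ~ 0: reconstruction ~ truth
        assert np.abs(out - t.trace).max() < 1e-6

    def test_jaggedness_fused_not_rougher_than_gep_only(self, nonlinear_dataset):
        cfg = GepConfig(population_size=40, n_generations=20, rng_seed=3)
        feats = [t.features for t in nonlinear_dataset]
        traces = [t.trace for t in nonlinear_dataset]
        model = train(feats, traces, cfg)

        def jaggedness(path):
            return np.abs(np.diff(path, n=2, axis=0)).mean()

        rough_gep, rough_fused = [], []
        for t in nonlinear_dataset:
            rough_gep.append(jaggedness(reconstruct_gep_only(t.features, model)))
            rough_fused.append(jaggedness(reconstruct(t.features, model)))
        # Kalman smoothing: fused paths are smoother on average
        assert np.mean(rough_fused) <= np.mean(rough_gep)
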