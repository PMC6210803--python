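"""R² scoring, trial splitting, and the Wilcoxon signed-rank test."""



import numpy as np
import pytest
from scipy import stats

from kfgep.evaluation import (
    ConstantSequenceError,
    r_squared,
    split_train_test,
    wilcoxon_signed_rank,
)
from kfgep.synthetic import generate_dataset


class TestRSquared:
    def test_perfect_prediction(self):
        t = np.array([1.0, 2, 3, 5])
        assert r_squared(t, t) == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        t = rng.normal(size=50)
        assert r_squared(t, 2 * t + 5) == pytest.approx(1.0)
        assert r_squared(2 * t + 5, t) == pytest.approx(1.0)

    def test_matches_hand_expanded_pearson_formula(self):
        t = np.array([1.0, 2, 3, 4])
        p = np.array([1.0, 2, 3, 100])
        n = 4
        num = n * (t * p).sum() - t.sum() * p.sum()
        den = np.sqrt(n * (t**2).sum() - t.sum() ** 2) * np.sqrt(
            n * (p**2).sum() - p.sum() ** 2
        )
        assert r_squared(t, p) == pytest.approx((num / den) ** 2, abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        a, b = rng.normal(size=(2, 30))
        assert r_squared(a, b) == pytest.approx(r_squared(b, a), abs=1e-14)

    def test_constant_sequence_is_an_error_not_zero(self):
        with pytest.raises(ConstantSequenceError):
            r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ConstantSequenceError):
            r_squared([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_validation(self):
        with pytest.raises(ValueError):
            r_squared([1, 2], [1, 2])
        with pytest.raises(ValueError):
            r_squared([1, 2, 3], [1, 2, 3, 4])


class TestSplit:
    def _dataset(self, n=40):
        return generate_dataset(
            symbols=("arch", "circle"), trials_per_symbol=n, n_points=6, rng_seed=0
        )

    def test_70_30_counts(self):
        tr, te = split_train_test(self._dataset(40), 0.7, rng_seed=1)
        assert len(tr) == 2 * 28 and len(te) == 2 * 12

    def test_disjoint_and_exhaustive(self):
        ds = self._dataset(10)
        tr, te = split_train_test(ds, 0.7, rng_seed=2)
        ids = lambda s: {(t.symbol_id, t.trial_id) for t in s}
        assert ids(tr) & ids(te) == set()
        assert ids(tr) | ids(te) == ids(ds)

    def test_deterministic_given_seed(self):
        ds = self._dataset(10)
        a = split_train_test(ds, 0.7, rng_seed=3)
        b = split_train_test(ds, 0.7, rng_seed=3)
        assert [t.trial_id for t in a[0]] == [t.trial_id for t in b[0]]

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(self._dataset(1), 0.7, rng_seed=0)


from _oracles import brute_force_signed_rank_p  # noqa: E402


class TestWilcoxon:
    def test_all_equal_pairs_is_an_error(self):
        a = np.arange(6.0)
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(a, a)

    def test_six_positive_differences_exact_p(self):
        b = np.zeros(6)
        a = np.arange(1.0, 7.0)
        w, p = wilcoxon_signed_rank(a, b, alternative="greater")
        assert w == pytest.approx(21.0)
        assert p == pytest.approx(1 / 64)

    @pytest.mark.parametrize("n", [5, 6, 7, 8, 9, 10])
    @pytest.mark.parametrize("alternative", ["greater", "less"])
    def test_exact_path_matches_enumeration(self, n, alternative):
        rng = np.random.default_rng(n * 17 + (0 if alternative == "greater" else 1))
        for _ in range(10):
            d = np.round(rng.normal(size=n), 2)
            d[d == 0] = 0.5
            a = d
            b = np.zeros(n)
            _, p = wilcoxon_signed_rank(a, b, alternative=alternative)
            assert p == pytest.approx(brute_force_signed_rank_p(d, alternative))

    def test_tie_free_exact_matches_scipy(self, rng):
        for _ in range(20):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            if np.unique(np.abs(a - b)).size < 12:
                continue
            _, p = wilcoxon_signed_rank(a, b, alternative="greater")
            ref = stats.wilcoxon(a, b, alternative="greater", method="exact")
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_large_sample_normal_approximation_is_close_to_scipy(self, rng):
        a = rng.normal(0.3, 1, size=60)
        b = rng.normal(0.0, 1, size=60)
        _, p = wilcoxon_signed_rank(a, b, alternative="greater")
        ref = stats.wilcoxon(
            a, b, alternative="greater", method="approx", correction=True
        )
        assert p == pytest.approx(ref.pvalue, rel=0.05)

    def test_p_values_in_unit_interval(self, rng):
        for _ in range(20):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            for alt in ("greater", "less", "two-sided"):
                _, p = wilcoxon_signed_rank(a, b, alternative=alt)
                assert 0 < p <= 1


class TestRunExperiment:
    def test_single_symbol_within_equals_between(self, linear_dataset):
        """With one symbol the two designs train identical models."""
        from kfgep.evaluation import run_experiment
        from kfgep.gep import GepConfig

        one = [t for t in linear_dataset if t.symbol_id == "arch"]
        cfg = GepConfig(population_size=20, n_generations=4)
        kw = dict(gep_config=cfg, rng_seed=3, n_splits=1)
        a = run_experiment(one, design="within", **kw)
        b = run_experiment(one, design="between", **kw)
        cols = ["symbol", "trial", "method", "r2_x", "r2_y"]
        assert a.records[cols].equals(b.records[cols])

    def test_report_shape_and_missing_handling(self, nonlinear_dataset):
        from kfgep.evaluation import run_experiment
        from kfgep.gep import GepConfig

        cfg = GepConfig(population_size=20, n_generations=4)
        rep = run_experiment(
            nonlinear_dataset, design="between", gep_config=cfg,
            rng_seed=1, n_splits=1,
        )
        assert set(rep.records["method"]) == {"KF-GEP", "KF", "GEP"}
        # every test trial scored once per method
        counts = rep.records.groupby("method").size()
        assert counts.nunique() == 1
        assert set(rep.comparisons) == {"KF-GEP_vs_KF", "KF-GEP_vs_GEP"}
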