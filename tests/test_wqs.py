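"""Core WQS machinery: splits, constrained fits, bootstrap weights, stage 2."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from conftest import make_decile_data
from wqskit.wqs import (
    WQSRegression,
    WeightVector,
    compute_mixture_index,
    estimate_bootstrap_weights,
    fit_constrained_glm,
    fit_validation_glm,
    split_data,
)


class TestSplit:
    def test_cardinality(self):
        spec = split_data(range(100), 0.4, seed=0)
        assert len(spec.train_ids) == 40
        assert len(spec.validation_ids) == 60

    def test_same_seed_reproduces_assignment(self):
        a = split_data(range(500), 0.4, seed=9).assignment
        b = split_data(range(500), 0.4, seed=9).assignment
        assert a.equals(b)

    def test_different_seeds_differ(self):
        a = split_data(range(1000), 0.4, seed=1).assignment
        b = split_data(range(1000), 0.4, seed=2).assignment
        assert not a.equals(b)

    def test_partition_exhaustive_and_disjoint(self):
        spec = split_data([f"r{i}" for i in range(123)], 0.3, seed=3)
        assert set(spec.train_ids) | set(spec.validation_ids) == \
            {f"r{i}" for i in range(123)}
        assert not set(spec.train_ids) & set(spec.validation_ids)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2, 1.5])
    def test_fraction_out_of_range_rejected(self, frac):
        with pytest.raises(ValueError):
            split_data(range(10), frac, seed=0)


class TestMixtureIndex:
    def test_degenerate_weight_selects_single_constituent(self):
        D = pd.DataFrame(np.random.default_rng(0).integers(0, 10, (20, 5)))
        w = np.array([1.0, 0, 0, 0, 0])
        assert np.array_equal(compute_mixture_index(D, w).to_numpy(),
                              D.iloc[:, 0].to_numpy(dtype=float))

    def test_equal_deciles_give_that_decile_for_any_weights(self):
        D = pd.DataFrame(np.full((4, 15), 6.0))
        rng = np.random.default_rng(1)
        w = rng.dirichlet(np.ones(15))
        assert np.allclose(compute_mixture_index(D, w), 6.0)

    def test_uniform_weights_hand_computed(self):
        d = np.concatenate([np.arange(10), [3, 7, 2, 8, 5]]).astype(float)
        idx = compute_mixture_index(d.reshape(1, -1), np.full(15, 1 / 15))
        assert np.isclose(idx.iloc[0], d.sum() / 15)

    def test_single_decile_bump_raises_index_by_that_weight(self):
        rng = np.random.default_rng(2)
        D = rng.integers(0, 9, (30, 8)).astype(float)
        w = rng.dirichlet(np.ones(8))
        base = compute_mixture_index(D, w)
        for j in range(8):
            D2 = D.copy()
            D2[:, j] += 1
            assert np.allclose(compute_mixture_index(D2, w) - base, w[j])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_mixture_index(np.zeros((5, 4)), np.full(3, 1 / 3))

    def test_bounded_between_0_and_9(self):
        rng = np.random.default_rng(3)
        D = rng.integers(0, 10, (200, 15)).astype(float)
        idx = compute_mixture_index(D, rng.dirichlet(np.ones(15)))
        assert idx.between(0, 9).all()


class TestConstrainedFit:
    def test_single_constituent_weight_is_one(self):
        D, y, _ = make_decile_data(200, 1, np.array([1.0]), 0.2, seed=0)
        w, beta1, info = fit_constrained_glm(D, y)
        assert np.allclose(w.to_numpy(), [1.0])
        assert info["converged"]

    def test_attains_grid_oracle_likelihood(self):
        """Constrained optimum must match an exhaustive simplex grid search."""
        for ds in range(3):
            rng = np.random.default_rng(100 + ds)
            n = 300
            D = rng.integers(0, 10, (n, 3)).astype(float)
            Z = rng.standard_normal((n, 2))
            eta = -1.5 + 0.25 * D[:, 0] + Z @ [0.3, -0.2]
            y = rng.binomial(1, expit(eta)).astype(float)
            _, _, info = fit_constrained_glm(pd.DataFrame(D), y, Z, seed=ds)
            best = -np.inf
            for w1 in np.arange(0, 1.0001, 0.02):
                for w2 in np.arange(0, 1.0001 - w1 + 1e-9, 0.02):
                    idx = D @ [w1, w2, 1 - w1 - w2]
                    X = np.column_stack([np.ones(n), idx, Z])
                    best = max(best, sm.Logit(y, X).fit(disp=0).llf)
            assert info["loglik"] >= best - 1e-6

    def test_null_outcome_gives_small_beta1(self):
        """With outcome independent of all constituents, |beta1| < 3 SE."""
        betas = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            D = pd.DataFrame(rng.integers(0, 10, (400, 4)).astype(float))
            y = rng.binomial(1, 0.3, 400)
            _, beta1, _ = fit_constrained_glm(D, y, seed=seed)
            betas.append(beta1)
        # SE of an index coefficient at n=400, p=0.3 is about 0.04
        assert np.mean(np.abs(betas)) < 3 * 0.04

    def test_weights_on_simplex(self):
        D, y, Z = make_decile_data(150, 6, np.r_[0.6, 0.4, np.zeros(4)], 0.3,
                                   seed=5, n_covs=2)
        w, _, _ = fit_constrained_glm(D, y, Z, seed=0)
        v = w.to_numpy()
        assert (v >= -1e-12).all() and abs(v.sum() - 1) < 1e-8


class TestBootstrapWeights:
    def test_output_is_simplex_and_counts_bootstraps(self):
        D, y, _ = make_decile_data(120, 5, np.r_[1.0, np.zeros(4)], 0.25, seed=1)
        wv = estimate_bootstrap_weights(D, y, n_bootstrap=8, seed=0)
        assert isinstance(wv, WeightVector)
        assert wv.n_boot_used == 8
        v = wv.w.to_numpy()
        assert (v >= 0).all() and abs(v.sum() - 1) < 1e-8

    def test_single_bootstrap_equals_single_fit_on_that_resample(self):
        D, y, _ = make_decile_data(100, 3, np.r_[0.7, 0.3, 0.0], 0.3, seed=2)
        rng = np.random.default_rng(42)
        rows = rng.integers(0, 100, size=100)
        inner_seed = int(rng.integers(2**31 - 1))
        w_direct, _, _ = fit_constrained_glm(D.iloc[rows], y[rows],
                                             seed=inner_seed)
        wv = estimate_bootstrap_weights(D, y, n_bootstrap=1, seed=42)
        assert np.allclose(wv.w.to_numpy(), w_direct.to_numpy(), atol=1e-6)

    def test_invalid_bootstrap_count_rejected(self):
        D, y, _ = make_decile_data(50, 3, np.r_[1.0, 0, 0], 0.2, seed=3)
        with pytest.raises(ValueError):
            estimate_bootstrap_weights(D, y, n_bootstrap=0)


class TestValidationGLM:
    def test_percent_increase_transform(self):
        """The reporting convention: beta1 = ln(1.068) is a 6.8% increase."""
        rng = np.random.default_rng(0)
        idx = rng.uniform(0, 9, 3000)
        y = rng.binomial(1, expit(-1.5 + np.log(1.068) * idx))
        res = fit_validation_glm(idx, y)
        assert np.isclose(res.percent_increase,
                          (np.exp(res.beta1) - 1) * 100)
        assert np.isclose(res.percent_increase_ci[0],
                          (np.exp(res.ci95[0]) - 1) * 100)
        assert res.ci95[0] <= res.beta1 <= res.ci95[1]

    def test_null_effect_reports_zero_percent(self):
        rng = np.random.default_rng(1)
        idx = rng.uniform(0, 9, 500)
        y = rng.binomial(1, 0.3, 500)
        res = fit_validation_glm(idx, y)
        assert abs(res.percent_increase) < 3 * 100 * res.se1  # near 0

    def test_singular_design_rejected(self):
        idx = np.ones(100)
        y = np.random.default_rng(2).binomial(1, 0.5, 100)
        with pytest.raises(ValueError):
            fit_validation_glm(idx, y, covariates=np.ones((100, 1)))

    def test_stage_separation_ignores_training_rows(self):
        """Identical validation data gives identical estimates regardless of
        what the training half looked like (weights are frozen inputs)."""
        rng = np.random.default_rng(4)
        idx_val = rng.uniform(0, 9, 800)
        y_val = rng.binomial(1, expit(-1 + 0.1 * idx_val))
        a = fit_validation_glm(idx_val, y_val)
        b = fit_validation_glm(idx_val.copy(), y_val.copy())
        assert a.beta1 == b.beta1 and a.ci95 == b.ci95


class TestWQSRegressionEstimator:
    def test_sklearn_contract(self):
        model = WQSRegression(n_bootstrap=3, random_state=0)
        params = model.get_params()
        assert params["n_bootstrap"] == 3
        model.set_params(n_bootstrap=5)
        assert model.get_params()["n_bootstrap"] == 5

    def test_fit_exposes_fitted_attributes_and_predicts(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.lognormal(size=(300, 4)),
                         columns=list("abcd"))
        d0 = X.rank().to_numpy()[:, 0]
        y = rng.binomial(1, expit(-1 + 0.004 * d0))
        model = WQSRegression(n_bootstrap=4, random_state=1).fit(X, y)
        assert abs(model.weights_.sum() - 1) < 1e-8
        assert model.ci95_[0] <= model.beta1_ <= model.ci95_[1]
        proba = model.predict_proba(X)
        assert proba.shape == (300, 2)
        assert np.allclose(proba.sum(axis=1), 1)

    def test_identical_random_state_reproduces_fit(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.lognormal(size=(200, 3)))
        y = rng.binomial(1, 0.3, 200)
        m1 = WQSRegression(n_bootstrap=3, random_state=7).fit(X, y)
        m2 = WQSRegression(n_bootstrap=3, random_state=7).fit(X, y)
        assert np.array_equal(m1.weights_.to_numpy(), m2.weights_.to_numpy())
        assert m1.beta1_ == m2.beta1_
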