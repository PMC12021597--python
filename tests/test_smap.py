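"""Tests for the regularized S-map: weights, solver, Jacobian inference."""

import numpy as np
import pandas as pd
import pytest

from commdyn import (
    CommunityTimeSeries,
    SMapHyperparams,
    benchmark_glv_params,
    infer_interactions,
    linear_benchmark_system,
    simulate_glv,
    smap_weights,
    standardize_series,
    summarize_interactions,
    tune_hyperparams,
    weighted_elastic_net,
)
from commdyn.synthetic import random_stable_params


def random_series(rng, n_taxa=5, n_time=30) -> CommunityTimeSeries:
    return CommunityTimeSeries(
        rng.normal(size=(n_taxa, n_time)),
        np.arange(n_time),
        [f"t{i}" for i in range(n_taxa)],
        standardized=True,
    )


def weight_oracle(series, target_index, theta):
    """Direct elementwise evaluation of the locality-weight formula."""
    states = series.abundances.T
    target = states[target_index]
    dists = [float(np.linalg.norm(states[n] - target)) for n in range(len(states) - 1)]
    mean_dist = sum(dists) / len(dists)
    if theta == 0:
        return np.ones(len(dists))
    return np.array([np.exp(-theta * d / mean_dist) for d in dists])


def net_objective(X, y, w, coef, intercept, lam, alpha, n_factor):
    resid = y - intercept - X @ coef
    return (w * resid**2).sum() / n_factor + lam * (
        alpha * (coef**2).sum() + (1 - alpha) * np.abs(coef).sum()
    )


def fista_oracle(X, y, w, lam, alpha, n_factor, n_iter=20000):
    """Independent proximal-gradient (FISTA) minimizer of the same objective,
    with the intercept handled by weighted centering."""
    wsum = w.sum()
    xm = (w[:, None] * X).sum(axis=0) / wsum
    ym = (w * y).sum() / wsum
    Xc, yc = X - xm, y - ym
    N = n_factor
    l1, l2 = lam * (1 - alpha), lam * alpha
    gram = (Xc * (w / N)[:, None]).T @ Xc
    L = 2 * np.linalg.eigvalsh(gram).max() + 2 * l2
    step = 1.0 / L
    c = np.zeros(X.shape[1])
    z = c.copy()
    t_k = 1.0
    for _ in range(n_iter):
        grad = -2.0 * Xc.T @ ((w / N) * (yc - Xc @ z)) + 2 * l2 * z
        u = z - step * grad
        c_new = np.sign(u) * np.maximum(np.abs(u) - step * l1, 0.0)
        t_next = (1 + np.sqrt(1 + 4 * t_k**2)) / 2
        z = c_new + (t_k - 1) / t_next * (c_new - c)
        c, t_k = c_new, t_next
    intercept = ym - xm @ c
    return c, intercept


class TestStandardize:
    def test_constant_taxon_removed(self):
        x = np.vstack([np.ones(10), np.random.default_rng(0).normal(2, 1, 10)])
        series = CommunityTimeSeries(x, np.arange(10), ["const", "var"], standardized=True)
        out, means, sds = standardize_series(series)
        assert out.taxon_ids == ["var"]

    def test_round_trip_recovers_input(self, rng):
        series = random_series(rng)
        out, means, sds = standardize_series(series)
        recon = out.abundances * sds.to_numpy()[:, None] + means.to_numpy()[:, None]
        np.testing.assert_allclose(recon, series.abundances, atol=1e-12)

    def test_already_standardized_unchanged(self, rng):
        z = rng.normal(size=(3, 20))
        z = (z - z.mean(1, keepdims=True)) / z.std(1, keepdims=True)
        series = CommunityTimeSeries(z, np.arange(20), list("abc"), standardized=True)
        out, _, _ = standardize_series(series)
        np.testing.assert_allclose(out.abundances, z, atol=1e-12)

    def test_all_constant_rejected(self):
        x = np.ones((2, 5))
        series = CommunityTimeSeries(x, np.arange(5), ["a", "b"])
        with pytest.raises(ValueError):
            standardize_series(series)


class TestSmapWeights:
    def test_theta_zero_gives_uniform_ones(self, rng):
        series = random_series(rng)
        np.testing.assert_array_equal(smap_weights(series, 10, 0.0), 1.0)

    def test_equal_distances_give_exp_minus_theta(self):
        # orthogonal unit states: every training state is at distance
        # sqrt(2) from the last state, which has no successor
        x = np.eye(5)
        series = CommunityTimeSeries(x, np.arange(5), [f"t{i}" for i in range(5)])
        w = smap_weights(series, 4, theta=1.5)
        np.testing.assert_allclose(w, np.exp(-1.5))

    def test_target_transition_weight_is_one(self, rng):
        series = random_series(rng)
        w = smap_weights(series, 7, theta=2.0)
        assert w[7] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_elementwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        series = random_series(rng, n_taxa=5, n_time=25)
        for theta in (0.0, 0.5, 2.0, 8.0):
            for target in (0, 10, 24):
                w = smap_weights(series, target, theta)
                np.testing.assert_allclose(w, weight_oracle(series, target, theta), atol=1e-14)

    def test_identical_states_rejected(self):
        x = np.ones((2, 6)) * 3.0
        series = CommunityTimeSeries(x, np.arange(6), ["a", "b"])
        with pytest.raises(ValueError):
            smap_weights(series, 0, theta=1.0)


class TestWeightedElasticNet:
    def test_unregularized_limit_equals_ols(self, rng):
        X = rng.normal(size=(60, 5))
        beta = rng.normal(size=5)
        y = X @ beta + 0.7
        fit = weighted_elastic_net(X, y, np.ones(60), SMapHyperparams(0.0, 0.0, 0.5))
        np.testing.assert_allclose(fit["coef"], beta, atol=1e-8)
        assert fit["intercept"] == pytest.approx(0.7, abs=1e-8)

    def test_weighted_ols_limit(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        w = rng.uniform(0.1, 1.0, 50)
        fit = weighted_elastic_net(X, y, w, SMapHyperparams(0.0, 0.0, 0.5))
        # weighted least squares closed form with intercept column
        Xa = np.hstack([np.ones((50, 1)), X])
        beta = np.linalg.solve((Xa * w[:, None]).T @ Xa, (Xa * w[:, None]).T @ y)
        assert fit["intercept"] == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(fit["coef"], beta[1:], atol=1e-8)

    def test_large_lasso_penalty_zeroes_coefficients(self, rng):
        X = rng.normal(size=(40, 4))
        y = rng.normal(size=40)
        fit = weighted_elastic_net(X, y, np.ones(40), SMapHyperparams(0.0, 50.0, 0.0))
        np.testing.assert_array_equal(fit["coef"], 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_objective_matches_fista_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 60, 8
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + rng.normal(0, 0.5, n)
        w = rng.uniform(0.05, 1.0, n)
        hyper = SMapHyperparams(theta=0.0, lam=0.1, alpha=0.5)
        fit = weighted_elastic_net(X, y, w, hyper)
        c_o, b_o = fista_oracle(X, y, w, 0.1, 0.5, n)
        obj_fit = net_objective(X, y, w, fit["coef"], fit["intercept"], 0.1, 0.5, n)
        obj_oracle = net_objective(X, y, w, c_o, b_o, 0.1, 0.5, n)
        assert obj_fit == pytest.approx(obj_oracle, abs=1e-6)
        assert obj_fit <= obj_oracle + 1e-6

    def test_objective_nonincreasing_across_sweeps(self, rng):
        """Track the objective sweep by sweep via repeated 1-sweep calls."""
        n, p = 40, 6
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        w = rng.uniform(0.1, 1.0, n)
        hyper = SMapHyperparams(0.0, 0.2, 0.3)
        import warnings

        coef = np.zeros(p)
        prev = np.inf
        for _ in range(30):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # 1-sweep calls report non-convergence
                fit = weighted_elastic_net(X, y, w, hyper, max_iter=1, coef_init=coef)
            obj = net_objective(X, y, w, fit["coef"], fit["intercept"], 0.2, 0.3, n)
            assert obj <= prev + 1e-12
            prev = obj
            coef = fit["coef"]

    def test_reported_objective_is_consistent(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        w = np.ones(30)
        fit = weighted_elastic_net(X, y, w, SMapHyperparams(0.0, 0.05, 0.5))
        assert fit["objective"] == pytest.approx(
            net_objective(X, y, w, fit["coef"], fit["intercept"], 0.05, 0.5, 30)
        )


class TestInferInteractions:
    def test_global_limit_replicates_single_ols(self, rng):
        series = random_series(rng, 4, 40)
        jac = infer_interactions(series, SMapHyperparams(0.0, 0.0, 0.5), standardize=False)
        spread = np.abs(jac.values - jac.values[:, :, :1]).max()
        assert spread < 1e-7

    @pytest.mark.parametrize("seed", range(3))
    def test_linear_system_recovery(self, seed):
        series, a = linear_benchmark_system(seed)
        jac = infer_interactions(series, SMapHyperparams(0.0, 1e-6, 0.5), raw_scale=True)
        assert np.abs(jac.time_averaged() - a).max() < 0.05

    def test_uncoupled_taxa_have_small_offdiagonals(self):
        params = random_stable_params(2, seed=0, interaction_density=0.0)
        series = simulate_glv(params, 120, np.ones(2), seed=0)
        jac = infer_interactions(series, SMapHyperparams(0.0, 1e-4, 0.5))
        med = np.abs(np.median(jac.values, axis=2))
        assert max(med[0, 1], med[1, 0]) < min(med[0, 0], med[1, 1])

    def test_taxon_permutation_equivariance(self, rng):
        series = random_series(rng, 4, 35)
        hyper = SMapHyperparams(1.0, 0.01, 0.5)
        jac = infer_interactions(series, hyper)
        perm = [2, 0, 3, 1]
        permuted = CommunityTimeSeries(
            series.abundances[perm], series.time_stamps,
            [series.taxon_ids[i] for i in perm], standardized=True,
        )
        jac_perm = infer_interactions(permuted, hyper)
        np.testing.assert_allclose(
            jac_perm.values, jac.values[np.ix_(perm, perm)], atol=1e-6
        )

    def test_short_series_warns(self, rng):
        series = random_series(rng, 2, 6)
        with pytest.warns(UserWarning, match="shorter than 10"):
            infer_interactions(series, SMapHyperparams())


class TestTuneHyperparams:
    def test_single_point_grid_returned(self, rng):
        series = random_series(rng, 3, 20)
        hyper, table = tune_hyperparams(series, (1.0,), (0.01,), (0.5,))
        assert (hyper.theta, hyper.lam, hyper.alpha) == (1.0, 0.01, 0.5)
        assert len(table) == 1

    def test_linear_system_prefers_small_theta(self):
        series, _ = linear_benchmark_system(0, n_steps=80)
        hyper, table = tune_hyperparams(series, (0.0, 2.0, 8.0), (1e-4,), (0.5,))
        assert hyper.theta <= 2.0

    def test_nonlinear_system_prefers_positive_theta(self):
        # strongly state-dependent dynamics: coupled logistic-style maps
        rng = np.random.default_rng(7)
        x = np.empty((2, 120))
        x[:, 0] = [0.4, 0.3]
        for t in range(119):
            x1, x2 = x[:, t]
            x[0, t + 1] = x1 * (3.8 - 3.8 * x1 - 0.02 * x2) + rng.normal(0, 1e-3)
            x[1, t + 1] = x2 * (3.5 - 3.5 * x2 - 0.1 * x1) + rng.normal(0, 1e-3)
        series = CommunityTimeSeries(np.abs(x), np.arange(120), ["a", "b"])
        hyper, _ = tune_hyperparams(series, (0.0, 2.0), (1e-4,), (0.5,))
        assert hyper.theta > 0


class TestSummarize:
    def _constant_jacobian(self, j12, j21):
        values = np.zeros((2, 2, 10))
        values[0, 1, :] = j12
        values[1, 0, :] = j21
        values[0, 0, :] = values[1, 1, :] = 0.5
        from commdyn.smap import JacobianSeries

        return JacobianSeries(
            values=values, intercepts=np.zeros((2, 10)),
            time_indices=np.arange(10), taxon_ids=["pred", "prey"],
            hyperparams=SMapHyperparams(),
        )

    def test_exploitation_flag_and_predator_label(self):
        table = summarize_interactions(self._constant_jacobian(+0.3, -0.2))
        row = table[(table.target == "pred") & (table.predictor == "prey")].iloc[0]
        assert row.pair_type == "exploitation"
        assert row.predator == "pred"

    def test_symmetric_positive_is_mutualistic_like(self):
        table = summarize_interactions(self._constant_jacobian(+0.3, +0.2))
        assert (table.pair_type == "mutualistic-like").all()

    def test_glv_predator_prey_pair_recovered(self):
        """The designated exploitation pair is recovered on a strong-signal
        seed (the aggregate 50-seed rate is checked in the acceptance suite)."""
        from commdyn.synthetic import BENCHMARK_PREDATOR_PREY_PAIR

        params = benchmark_glv_params()
        pred, prey = BENCHMARK_PREDATOR_PREY_PAIR
        series = simulate_glv(params, 150, np.ones(8), seed=1)
        jac = infer_interactions(series, SMapHyperparams(1.0, 1e-4, 0.5))
        table = summarize_interactions(jac)
        row = table[
            (table.target == series.taxon_ids[pred])
            & (table.predictor == series.taxon_ids[prey])
        ].iloc[0]
        assert row.pair_type == "exploitation"
        assert row.predator == series.taxon_ids[pred]
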