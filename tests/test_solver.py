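"""Coordinate-descent solver, OLS, adaptive lasso, and stepwise baseline."""

import numpy as np
import pytest
from sklearn.linear_model import ElasticNet, Lasso

from penselect import (
    Dataset,
    PenaltySpec,
    fit_adaptive_lasso,
    fit_ols,
    fit_penalized,
    fit_stepwise,
    threshold,
)
from penselect.solver import Standardized, penalized_objective

from conftest import make_dataset, make_orthonormal_dataset

ALL_SPECS = [
    PenaltySpec("lasso", 0.1),
    PenaltySpec("elastic_net", 0.1, alpha=0.5),
    PenaltySpec("scad", 0.1),
    PenaltySpec("mcp", 0.1),
]


class TestDataset:
    def test_rejects_constant_column(self, rng):
        X = rng.standard_normal((30, 3))
        X[:, 1] = 2.0
        with pytest.raises(ValueError, match="constant"):
            Dataset(X, rng.standard_normal(30), ["a", "b", "c"])

    def test_rejects_n_le_p(self, rng):
        X = rng.standard_normal((3, 5))
        with pytest.raises(ValueError, match="n > p"):
            Dataset(X, rng.standard_normal(3), list("abcde"))

    def test_csv_round_trip(self, dataset, tmp_path):
        path = tmp_path / "d.csv"
        dataset.to_csv(path, header_lines=["written by test"])
        back = Dataset.from_csv(path, outcome="y")
        assert back.names == dataset.names
        np.testing.assert_allclose(back.X, dataset.X)
        np.testing.assert_allclose(back.y, dataset.y)


class TestFitPenalized:
    @pytest.mark.parametrize("family,kw", [
        ("lasso", {}), ("scad", {}), ("mcp", {}), ("elastic_net", {"alpha": 0.5}),
    ])
    def test_lambda_zero_recovers_ols(self, dataset, family, kw):
        res = fit_penalized(dataset, PenaltySpec(family, 0.0, **kw))
        ols = fit_ols(dataset)
        np.testing.assert_allclose(res.beta, ols.beta, atol=1e-8)
        assert res.df == dataset.p

    def test_huge_lambda_selects_nothing(self, dataset):
        res = fit_penalized(dataset, PenaltySpec("lasso", 1e6))
        assert res.df == 0
        assert np.all(res.beta == 0.0)
        assert res.intercept == pytest.approx(dataset.y.mean())

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.family)
    def test_orthonormal_fit_equals_coordinatewise_threshold(self, rng, spec):
        data = make_orthonormal_dataset(rng, n=50, p=3, beta=[0.5, -0.2, 0.05])
        pre = Standardized(data)
        res = fit_penalized(data, spec, pre=pre)
        beta_std = res.beta * pre.sd
        for j in range(3):
            assert beta_std[j] == pytest.approx(threshold(pre.c[j], spec), abs=1e-8)

    def test_p2_lasso_matches_nested_grid_minimizer(self, rng):
        """Coordinate descent hits the global lasso optimum (convex case)."""
        for trial in range(50):
            data = make_dataset(rng, n=40, p=2, beta=rng.normal(0, 1, 2))
            lam = rng.uniform(0.02, 0.5)
            spec = PenaltySpec("lasso", lam)
            pre = Standardized(data)
            res = fit_penalized(data, spec, pre=pre)
            lo, hi = np.full(2, -4.0), np.full(2, 4.0)
            for _ in range(5):
                g0 = np.linspace(lo[0], hi[0], 21)
                g1 = np.linspace(lo[1], hi[1], 21)
                B0, B1 = np.meshgrid(g0, g1, indexing="ij")
                obj = (
                    0.5 * (pre.var_y - 2 * (pre.c[0] * B0 + pre.c[1] * B1)
                           + B0**2 + B1**2 + 2 * pre.G[0, 1] * B0 * B1)
                    + lam * (np.abs(B0) + np.abs(B1))
                )
                k0, k1 = np.unravel_index(np.argmin(obj), obj.shape)
                lo = np.array([g0[max(k0 - 1, 0)], g1[max(k1 - 1, 0)]])
                hi = np.array([g0[min(k0 + 1, 20)], g1[min(k1 + 1, 20)]])
            best = np.array([g0[k0], g1[k1]])
            np.testing.assert_allclose(res.beta * pre.sd, best, atol=1e-3)

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.family)
    def test_objective_monotone_descent(self, dataset, spec):
        res = fit_penalized(dataset, spec.with_lam(0.15), keep_history=True)
        hist = np.array(res.history)
        assert np.all(np.diff(hist) <= 1e-12)

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.family)
    def test_warm_restart_is_fixed_point(self, dataset, spec):
        res = fit_penalized(dataset, spec.with_lam(0.2))
        again = fit_penalized(dataset, spec.with_lam(0.2), init=res.beta)
        np.testing.assert_allclose(again.beta, res.beta, atol=1e-6)
        assert again.n_sweeps <= 2

    def test_standardization_round_trip_predictions(self, rng):
        # identical predictions whether covariates arrive raw or pre-scaled
        data = make_dataset(rng, n=60, p=4, beta=[1.0, 0.0, -2.0, 0.3])
        scales = np.array([1e-3, 1.0, 1e2, 1e5])
        scaled = Dataset(data.X * scales, data.y, data.names)
        spec = PenaltySpec("lasso", 0.1)
        r1 = fit_penalized(data, spec)
        r2 = fit_penalized(scaled, spec)
        np.testing.assert_allclose(r1.predict(data.X), r2.predict(scaled.X), atol=1e-10)
        np.testing.assert_allclose(r1.beta, r2.beta * scales, atol=1e-10)

    def test_exact_zeros_not_truncation(self, dataset):
        res = fit_penalized(dataset, PenaltySpec("lasso", 0.3))
        assert set(np.flatnonzero(res.beta)) == set(res.selected)
        assert np.all(res.beta[np.setdiff1d(np.arange(dataset.p), res.selected)] == 0.0)

    def test_matches_sklearn_lasso_and_enet(self, rng):
        """Independent solver cross-check on the shared convex objectives."""
        data = make_dataset(rng, n=120, p=6, beta=[1, 0, -0.5, 0, 0.2, 0])
        pre = Standardized(data)
        Xs = (data.X - pre.mu) / pre.sd
        yc = data.y - data.y.mean()
        lam = 0.13
        ours = fit_penalized(data, PenaltySpec("lasso", lam), pre=pre)
        sk = Lasso(alpha=lam, fit_intercept=False, tol=1e-12).fit(Xs, yc)
        np.testing.assert_allclose(ours.beta * pre.sd, sk.coef_, atol=1e-6)

        alpha = 0.4  # ours: lam*(alpha|b| + (1-alpha) b^2)
        sk_alpha = lam * alpha + 2 * lam * (1 - alpha)
        l1_ratio = lam * alpha / sk_alpha
        ours = fit_penalized(data, PenaltySpec("elastic_net", lam, alpha=alpha), pre=pre)
        sk = ElasticNet(alpha=sk_alpha, l1_ratio=l1_ratio, fit_intercept=False, tol=1e-12).fit(Xs, yc)
        np.testing.assert_allclose(ours.beta * pre.sd, sk.coef_, atol=1e-6)

    def test_weight_zero_coordinate_never_penalized(self, rng):
        data = make_dataset(rng, n=60, p=3, beta=[0.5, 0, 0])
        w = np.array([0.0, 1.0, 1.0])
        res = fit_penalized(data, PenaltySpec("adaptive_lasso", 5.0, weights=w))
        assert 0 in res.selected  # unpenalized coordinate survives any lambda


class TestFitOLS:
    def test_noiseless_single_regressor(self, rng):
        X = rng.standard_normal((30, 2))
        data = Dataset(X, 2.0 * X[:, 0], ["a", "b"])
        res = fit_ols(data, support=[0])
        assert res.beta[0] == pytest.approx(2.0)
        assert res.beta[1] == 0.0
        np.testing.assert_allclose(res.predict(X), data.y, atol=1e-10)

    def test_empty_support_gives_mean_model(self, dataset):
        res = fit_ols(dataset, support=[])
        assert np.all(res.beta == 0.0)
        assert res.intercept == pytest.approx(dataset.y.mean())

    def test_matches_normal_equations(self, rng):
        data = make_dataset(rng, n=20, p=3, beta=[1, 2, 3])
        res = fit_ols(data)
        Xa = np.column_stack([np.ones(20), data.X])
        coef = np.linalg.solve(Xa.T @ Xa, Xa.T @ data.y)
        assert res.intercept == pytest.approx(coef[0], abs=1e-10)
        np.testing.assert_allclose(res.beta, coef[1:], atol=1e-10)


class TestAdaptiveLasso:
    def test_unit_pilot_weights_reduce_to_plain_lasso(self, rng):
        data = make_orthonormal_dataset(rng, n=60, p=3, beta=[0.4, -0.3, 0.2])
        pre = Standardized(data)
        w = np.ones(3)
        res_w = fit_penalized(data, PenaltySpec("adaptive_lasso", 0.1, weights=w), pre=pre)
        res_l = fit_penalized(data, PenaltySpec("lasso", 0.1), pre=pre)
        np.testing.assert_allclose(res_w.beta, res_l.beta, atol=1e-10)

    def test_orthonormal_coordinates_soft_thresholded_at_scaled_level(self, rng):
        data = make_orthonormal_dataset(rng, n=50, p=3, beta=[0.8, -0.4, 0.1])
        pre = Standardized(data)
        pilot = fit_ols(data, pre=pre)
        pilot_std = np.abs(pilot.beta * pre.sd)
        lam = 0.05
        res = fit_adaptive_lasso(data, lam, gamma=1.0)
        beta_std = res.beta * pre.sd
        for j in range(3):
            lvl = lam / pilot_std[j]
            expect = np.sign(pre.c[j]) * max(abs(pre.c[j]) - lvl, 0.0)
            assert beta_std[j] == pytest.approx(expect, abs=1e-8)

    def test_huge_pilot_coefficient_essentially_unpenalized(self, rng):
        data = make_orthonormal_dataset(rng, n=50, p=3, beta=[50.0, 0.0, 0.0], sigma=0.1)
        pre = Standardized(data)
        res = fit_adaptive_lasso(data, 0.5)
        assert (res.beta * pre.sd)[0] == pytest.approx(pre.c[0], rel=1e-3)


class TestStepwise:
    def test_null_selects_empty_most_seeds(self):
        hits = 0
        rng = np.random.default_rng(7)
        n_seeds = 100
        for _ in range(n_seeds):
            data = make_dataset(rng, n=500, p=10)
            if fit_stepwise(data, criterion="bic").df == 0:
                hits += 1
        assert hits >= 0.8 * n_seeds

    def test_dominant_signal_always_included(self, rng):
        data = make_dataset(rng, n=200, p=5, beta=[5, 0, 0, 0, 0], sigma=0.5)
        res = fit_stepwise(data)
        assert 0 in res.selected

    def test_forward_entry_follows_marginal_correlation(self, rng):
        data = make_orthonormal_dataset(rng, n=90, p=3, beta=[0.3, 0.9, 0.6], sigma=0.05)
        res = fit_stepwise(data)
        pre = Standardized(data)
        expected = list(np.argsort(-np.abs(pre.c)))
        assert res.entry_order == expected

    def test_pvalue_mode_threshold_order_enforced(self, dataset):
        with pytest.raises(ValueError):
            fit_stepwise(dataset, criterion="pvalue", p_enter=0.2, p_remove=0.1)

    def test_pvalue_mode_finds_signal(self, rng):
        data = make_dataset(rng, n=300, p=6, beta=[0, 0, 3, 0, 0, 0], sigma=1.0)
        res = fit_stepwise(data, criterion="pvalue")
        assert 2 in res.selected

    def test_deterministic(self, dataset):
        a = fit_stepwise(dataset)
        b = fit_stepwise(dataset)
        assert list(a.selected) == list(b.selected)


class TestObjectiveHelper:
    def test_matches_direct_computation(self, rng):
        data = make_dataset(rng, n=40, p=3, beta=[1, -1, 0])
        pre = Standardized(data)
        spec = PenaltySpec("scad", 0.3)
        b = rng.normal(0, 1, 3)
        Xs = (data.X - pre.mu) / pre.sd
        yc = data.y - data.y.mean()
        def scad_pen(t, lam, a):
            t = abs(t)
            if t <= lam:
                return lam * t
            if t <= a * lam:
                return (2 * a * lam * t - t**2 - lam**2) / (2 * (a - 1))
            return 0.5 * (a + 1) * lam**2

        direct = 0.5 * np.sum((yc - Xs @ b) ** 2) / data.n + sum(
            scad_pen(t, spec.lam, spec.a) for t in b
        )
        assert penalized_objective(pre, b, spec) == pytest.approx(direct, rel=1e-10)
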