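import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from oracles import classical_partial_F, star_newick

from glandcov import (
    PhyloCovariance,
    Tree,
    anova_type3,
    complexity_regression,
    default_kda_calibration,
    pgls_fit,
    predict_response,
    responsive_regions,
    simulate_bm,
    simulate_tree,
)
from glandcov.errors import GlandcovError, RankDeficientError
from glandcov.treeops import gls_mean


def identity_cov(n):
    return PhyloCovariance(labels=[f"s{i}" for i in range(n)], C=np.eye(n))


class TestPGLSFit:
    def test_identity_cov_equals_ols(self, rng):
        n = 20
        X = rng.standard_normal((n, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.standard_normal(n)
        fit = pgls_fit(y[:, None], X, identity_cov(n))
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        assert np.allclose(fit.coefficients[:, 0], ols.params)
        assert fit.rss_full == pytest.approx(ols.ssr)

    def test_exact_linear_fit_has_zero_rss(self):
        tree = simulate_tree(10, seed=2)
        X = simulate_bm(tree, np.eye(2), seed=1)
        Y = X @ np.array([[1.0, 2.0], [3.0, -1.0]]) + 5.0
        fit = pgls_fit(Y, X, tree)
        assert fit.rss_full < 1e-18 * max(1.0, (Y**2).sum())

    def test_intercept_only_fits_gls_mean(self):
        tree = simulate_tree(8, seed=4)
        Y = simulate_bm(tree, np.eye(3), seed=2) + 2.0
        fit = pgls_fit(Y, np.empty((8, 0)), tree)
        C = fit.cov.C
        back = np.linalg.inv(fit.cov.E) @ fit.fitted  # back to species space
        assert np.allclose(back, np.tile(gls_mean(C, Y), (8, 1)))

    def test_collinear_design_raises(self, rng):
        X = rng.standard_normal((12, 2))
        X = np.column_stack([X, X[:, 0] * 2.0])
        with pytest.raises(RankDeficientError):
            pgls_fit(rng.standard_normal((12, 1)), X, identity_cov(12))


class TestAnovaTypeIII:
    def test_single_predictor_ss_equals_sequential(self, rng):
        n = 15
        X = rng.standard_normal((n, 1))
        y = 0.8 * X[:, 0] + rng.standard_normal(n)
        fit = pgls_fit(y[:, None], X, identity_cov(n))
        tab = anova_type3(fit, n_perm=9, seed=0)
        # with one term, type III SS = total fit improvement over intercept-only
        yc = y - y.mean()
        fit0_rss = float(yc @ yc)
        assert tab.table.loc[0, "SS"] == pytest.approx(fit0_rss - fit.rss_full)

    def test_pseudo_f_equals_classical_partial_f(self, rng):
        n = 25
        X = rng.standard_normal((n, 3))
        y = X @ [0.5, 0.0, -1.0] + rng.standard_normal(n)
        fit = pgls_fit(y[:, None], X, identity_cov(n))
        tab = anova_type3(fit, n_perm=9, seed=0)
        for j in range(3):
            assert tab.table.loc[j, "pseudo_F"] == pytest.approx(
                classical_partial_F(y, X, j), abs=1e-8
            )

    def test_type3_invariant_to_predictor_order(self, rng):
        tree = simulate_tree(14, seed=6)
        X = pd.DataFrame(
            simulate_bm(tree, np.eye(3), seed=1), index=tree.tips, columns=list("abc")
        )
        Y = simulate_bm(tree, np.eye(4), seed=2)
        t1 = anova_type3(pgls_fit(Y, X, tree), n_perm=99, seed=3)
        t2 = anova_type3(pgls_fit(Y, X[["c", "a", "b"]], tree), n_perm=99, seed=3)
        a = t1.table.set_index("term").loc[list("abc")]
        b = t2.table.set_index("term").loc[list("abc")]
        assert np.allclose(a["SS"], b["SS"])
        assert np.allclose(a["pseudo_F"], b["pseudo_F"])
        assert np.allclose(a["p_perm"], b["p_perm"])  # shared permutation stream

    def test_holm_adjustment_monotone(self, rng):
        tree = simulate_tree(16, seed=8)
        X = simulate_bm(tree, np.eye(4), seed=3)
        Y = simulate_bm(tree, np.eye(2), seed=4)
        tab = anova_type3(pgls_fit(Y, X, tree), n_perm=99, seed=0)
        adj = tab.p_adjusted()
        assert (adj.to_numpy() >= tab.table["p_perm"].to_numpy() - 1e-12).all()
        assert set(tab.significant_terms(adjust="holm")) <= set(
            tab.significant_terms(adjust="none")
        )


class TestPredictAndRegions:
    @pytest.fixture
    def fitted(self):
        tree = simulate_tree(12, seed=9)
        X = pd.DataFrame(
            np.abs(simulate_bm(tree, np.eye(2), seed=5)) + 0.1,
            index=tree.tips,
            columns=["focal", "other"],
        )
        Y = simulate_bm(tree, np.eye(30), seed=6)
        Y[:, 10:14] += 2.0 * X[["focal"]].to_numpy()
        return pgls_fit(Y, X, tree), X

    def test_prediction_affine_in_at_values(self, fitted):
        fit, X = fitted
        pred = predict_response(fit, "focal", [0.0, 1.0, 2.0])
        assert np.allclose(pred[2] - pred[1], pred[1] - pred[0])

    def test_centroid_prediction(self, fitted):
        fit, X = fitted
        x_mean = gls_mean(fit.cov.C, fit.X_raw)
        pred = predict_response(fit, "focal", [x_mean[0]])
        expected = np.concatenate([[1.0], x_mean]) @ fit.coefficients
        assert np.allclose(pred[0], expected)

    def test_known_effect_localized(self, fitted):
        fit, X = fitted
        lo, hi = X["focal"].min(), X["focal"].max()
        pred = predict_response(fit, "focal", [lo, hi])
        delta = pred[1] - pred[0]
        assert set(np.argsort(delta)[-4:]) == {10, 11, 12, 13}

    def test_unknown_term(self, fitted):
        with pytest.raises(GlandcovError):
            predict_response(fitted[0], "nope", [0.0])

    def test_rectangular_bump(self):
        lo = np.zeros(50)
        hi = np.zeros(50)
        hi[10:15] = 1.0
        rep = responsive_regions(lo, hi, min_run=2, frac_of_max=0.5)
        assert len(rep) == 1
        r = rep.regions[0]
        assert (r.start_bin, r.end_bin, r.delta) == (10, 14, 1.0)

    def test_flat_delta_degenerate(self):
        with pytest.warns(UserWarning):
            rep = responsive_regions(np.zeros(20), np.ones(20))
        assert len(rep) == 1 and rep.regions[0].start_bin == 0

    def test_three_bumps_threshold_arithmetic(self):
        delta = np.zeros(60)
        delta[5:9] = 1.0
        delta[20:24] = 0.8
        delta[40:44] = 0.1
        rep = responsive_regions(np.zeros(60), delta, min_run=2, frac_of_max=0.5)
        assert len(rep) == 2
        assert [r.start_bin for r in rep.regions] == [5, 20]  # sorted by |delta|

    def test_nonpositive_delta_empty(self):
        rep = responsive_regions(np.ones(10), np.zeros(10))
        assert len(rep) == 0

    def test_kda_bounds_attached(self):
        kda = default_kda_calibration(50)
        hi = np.zeros(50)
        hi[5:10] = 1.0
        rep = responsive_regions(np.zeros(50), hi, bin_kda=kda)
        r = rep.regions[0]
        assert r.start_kda == pytest.approx(kda[5]) and r.end_kda == pytest.approx(kda[9])
        assert r.start_kda > r.end_kda  # calibration runs high to low MW


class TestComplexityRegression:
    def test_slope_recovery_on_star_tree(self, rng):
        tree = Tree.from_newick(star_newick([f"t{i}" for i in range(30)], t=1.0))
        slopes, covered = [], 0
        for rep in range(50):
            r = np.random.default_rng(rep)
            x = r.standard_normal(30)
            y = 2.0 * x + 0.5 * r.standard_normal(30)
            res = complexity_regression(y, x, tree, n_perm=99, seed=rep)
            slopes.append(res.slope)
            # CI of the line at the x extremes should bracket the truth
            truth = res.intercept + 2.0 * res.x_grid
            covered += np.all((res.band_lo <= truth) & (truth <= res.band_hi))
        assert np.median(slopes) == pytest.approx(2.0, abs=0.15)
        assert covered >= 35  # 95% band covers the true line most of the time

    def test_exact_fit_reports_capped_statistics(self):
        tree = simulate_tree(10, seed=3)
        x = simulate_bm(tree, np.eye(1), seed=1).ravel()
        res = complexity_regression(x.copy(), x, tree, n_perm=99, seed=0)
        assert res.fit.rss_full < 1e-18
        assert np.isinf(res.anova.table.loc[0, "pseudo_F"])
        assert res.anova.table.loc[0, "p_perm"] == pytest.approx(1 / 100)
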