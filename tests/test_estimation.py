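"""OLS / probit / Heckman estimators against independent oracles."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import leadselect as ls
from leadselect.errors import (
    CollinearityError,
    SeparationError,
    UndefinedStatisticError,
)
from leadselect.features import DesignMatrix
from leadselect.synthetic import COHORT_CHILD, SamplingConfig


def design_from_arrays(X, y, clusters, names=None):
    names = names or [f"x{i}" for i in range(X.shape[1])]
    return DesignMatrix(
        X=pd.DataFrame(X, columns=names),
        y=pd.Series(y, name="y"),
        clusters=pd.Series(clusters),
        cohort="child",
        equation="outcome",
    )


class TestOLS:
    def test_exact_linear_fit(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        X = np.column_stack([x, np.ones(4)])
        d = design_from_arrays(X, 2 * x + 1, [0, 0, 1, 1], ["x", "const"])
        fit = ls.fit_ols(d)
        assert fit.params["x"] == pytest.approx(2.0)
        assert fit.params["const"] == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(6), rng.normal(size=(6, 2))])
        y = rng.normal(size=6)
        d = design_from_arrays(X, y, [0, 0, 1, 1, 2, 2], ["const", "a", "b"])
        fit = ls.fit_ols(d)
        oracle = np.linalg.inv(X.T @ X) @ X.T @ y
        np.testing.assert_allclose(fit.params.to_numpy(), oracle, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, child_fits):
        ols, _ = child_fits
        # recover the design used in the fixture fit
        assert ols.resid is not None
        # orthogonality is checked through the normal equations residual norm
        # |X'u| relative to |X'y| at machine precision on a fresh fit
        rng = np.random.default_rng(7)
        X = np.column_stack([np.ones(50), rng.normal(size=(50, 3))])
        y = rng.normal(size=50)
        d = design_from_arrays(X, y, np.arange(50) % 5, ["const", "a", "b", "c"])
        fit = ls.fit_ols(d)
        assert np.max(np.abs(X.T @ fit.resid)) < 1e-9 * np.max(np.abs(X.T @ y))

    def test_collinear_columns_are_named_not_dropped(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=10)
        X = np.column_stack([np.ones(10), a, 2 * a])
        d = design_from_arrays(X, rng.normal(size=10), np.arange(10) % 3, ["const", "a", "twice_a"])
        with pytest.raises(CollinearityError) as err:
            ls.fit_ols(d)
        assert "twice_a" in err.value.columns or "a" in err.value.columns

    def test_cr1_collapses_to_hc1_with_singleton_clusters(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(40), rng.normal(size=(40, 2))])
        y = X @ [1.0, 0.5, -0.3] + rng.normal(size=40)
        d = design_from_arrays(X, y, np.arange(40), ["const", "a", "b"])
        fit = ls.fit_ols(d)
        ref = sm.OLS(y, X).fit(cov_type="HC1")
        np.testing.assert_allclose(fit.bse.to_numpy(), ref.bse, rtol=1e-8)

    def test_cluster_covariance_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(60), rng.normal(size=(60, 2))])
        y = X @ [1.0, 0.5, -0.3] + rng.normal(size=60)
        groups = np.arange(60) % 8
        d = design_from_arrays(X, y, groups, ["const", "a", "b"])
        fit = ls.fit_ols(d)
        ref = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": groups})
        np.testing.assert_allclose(fit.bse.to_numpy(), ref.bse, rtol=1e-8)
        # P values use t with G-1 degrees of freedom
        expect_p = 2 * stats.t.sf(np.abs(fit.params / fit.bse), df=8 - 1)
        np.testing.assert_allclose(fit.pvalues.to_numpy(), expect_p, rtol=1e-12)

    def test_covariance_is_symmetric_psd(self, child_fits):
        ols, _ = child_fits
        cov = ols.cov.to_numpy()
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.linalg.eigvalsh(cov).min() > -1e-10


class TestProbit:
    def test_intercept_only_closed_form(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], dtype=float)
        d = design_from_arrays(np.ones((10, 1)), y, np.arange(10) % 2, ["const"])
        fit = ls.fit_probit(d)
        assert fit.params["const"] == pytest.approx(stats.norm.ppf(0.3), abs=1e-7)

    def test_loglike_matches_grid_search_oracle(self):
        x = np.array([-2.0, -1.5, -0.5, -0.2, 0.3, 0.9, 1.4, 2.2])
        y = np.array([0, 0, 1, 0, 1, 0, 1, 1], dtype=float)
        X = np.column_stack([np.ones(8), x])
        d = design_from_arrays(X, y, np.arange(8) % 2, ["const", "x"])
        fit = ls.fit_probit(d)

        def ll(a, b):
            z = a + b * x
            return np.sum(y * stats.norm.logcdf(z) + (1 - y) * stats.norm.logcdf(-z))

        # coarse-to-fine grid search, independent of the Newton path
        center, width = np.zeros(2), 4.0
        for _ in range(8):
            a_grid = np.linspace(center[0] - width, center[0] + width, 41)
            b_grid = np.linspace(center[1] - width, center[1] + width, 41)
            vals = np.array([[ll(a, b) for b in b_grid] for a in a_grid])
            i, j = np.unravel_index(np.argmax(vals), vals.shape)
            center, width = np.array([a_grid[i], b_grid[j]]), width / 8
        assert fit.loglike == pytest.approx(ll(*center), abs=1e-6)
        assert fit.loglike >= ll(*center) - 1e-9

    def test_matches_statsmodels_probit(self):
        smd = pytest.importorskip("statsmodels.discrete.discrete_model")
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(300), rng.normal(size=(300, 2))])
        y = (X @ [0.2, 0.8, -0.5] + rng.standard_normal(300) > 0).astype(float)
        d = design_from_arrays(X, y, np.arange(300) % 10, ["const", "a", "b"])
        fit = ls.fit_probit(d)
        ref = smd.Probit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params, atol=1e-6)
        assert fit.loglike == pytest.approx(ref.llf, abs=1e-8)

    def test_loglike_non_decreasing_over_iterations(self, survey_frame):
        child = survey_frame[survey_frame["cohort"] == COHORT_CHILD]
        fit = ls.fit_probit(ls.build_design(child, ls.ModelSpec.child_selection()))
        path = np.array(fit.loglike_path)
        assert np.all(np.diff(path) >= -1e-9)
        assert fit.probs.min() > 0 and fit.probs.max() < 1

    def test_single_class_outcome_rejected(self):
        d = design_from_arrays(np.ones((6, 1)), np.ones(6), np.arange(6) % 2, ["const"])
        with pytest.raises(ValueError):
            ls.fit_probit(d)

    def test_perfect_separation_detected(self):
        x = np.linspace(-3, 3, 30)
        y = (x > 0).astype(float)
        X = np.column_stack([np.ones(30), x])
        d = design_from_arrays(X, y, np.arange(30) % 3, ["const", "x"])
        with pytest.raises((SeparationError, Exception)):
            ls.fit_probit(d)


class TestInverseMills:
    def test_value_at_zero(self):
        assert ls.inverse_mills(0.0) == pytest.approx(math.sqrt(2 / math.pi), rel=1e-12)

    def test_deep_tail_matches_quadrature_oracle(self):
        z = -10.0
        tail, _ = integrate.quad(stats.norm.pdf, -np.inf, z)
        oracle = stats.norm.pdf(z) / tail
        assert ls.inverse_mills(z) == pytest.approx(oracle, rel=1e-9)
        assert np.isfinite(ls.inverse_mills(-500.0))

    def test_analytic_bounds(self):
        z = np.arange(-8.0, 8.5, 0.5)
        lam = ls.inverse_mills(z)
        assert np.all(lam > 0)
        assert np.all(lam > -z)


class TestHeckman:
    def test_constant_mills_ratio_reduces_to_ols(self):
        # with an intercept-only selection equation the Mills ratio is a
        # constant column and plays the role of the intercept: slopes must
        # equal the participant-only OLS slopes exactly
        rng = np.random.default_rng(6)
        n = 40
        X = rng.normal(size=(n, 2))
        y = X @ [0.7, -0.4] + 1.0 + 0.1 * rng.normal(size=n)
        clusters = np.arange(n) % 5
        out = design_from_arrays(X, y, clusters, ["a", "b"])
        sel = DesignMatrix(
            X=pd.DataFrame({"const": np.ones(n)}),
            y=pd.Series(np.r_[np.ones(n // 2), np.zeros(n // 2)][np.argsort(rng.random(n))]),
            clusters=pd.Series(clusters),
            cohort="child",
            equation="selection",
        )
        selected = sel.y == 1
        out_sel = DesignMatrix(
            X=out.X.loc[selected.to_numpy()],
            y=out.y.loc[selected.to_numpy()],
            clusters=out.clusters.loc[selected.to_numpy()],
            cohort="child",
            equation="outcome",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            heck = ls.fit_heckman_two_step(out_sel, sel)
        ols_X = np.column_stack([np.ones(int(selected.sum())), out_sel.X.to_numpy()])
        ref = np.linalg.lstsq(ols_X, out_sel.y.to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(
            heck.second_stage.params[["a", "b"]].to_numpy(), ref[1:], atol=1e-10
        )

    def test_missing_exclusion_restriction_warns(self, survey_frame):
        child = survey_frame[survey_frame["cohort"] == COHORT_CHILD]
        part = child[child["participated"] == 1]
        out = ls.build_design(part, ls.ModelSpec.child_outcome())
        sel = ls.build_design(child, ls.ModelSpec.child_selection())
        sel_no_excl = DesignMatrix(
            X=sel.X.drop(columns=["window_days"]),
            y=sel.y,
            clusters=sel.clusters,
            cohort="child",
            equation="selection",
        )
        with pytest.warns(UserWarning, match="exclusion"):
            ls.fit_heckman_two_step(out, sel_no_excl)

    def test_mills_ratio_positive_and_rows_match(self, child_fits):
        _, heck = child_fits
        assert (heck.imr > 0).all()
        assert heck.second_stage.n_obs == len(heck.imr)

    def test_correction_reduces_selection_bias(self):
        # with rho = 0.6 and selection strongly driven by distance, the
        # participant-only OLS distance slope is biased; the two-step
        # correction shrinks the bias (Monte-Carlo comparison)
        truth = ls.TruthParams(rho=0.6)
        truth.delta_child["log_distance"] = -0.5
        ols_est, heck_est = [], []
        for seed in range(40):
            hh, ind = ls.generate_survey(
                SamplingConfig(households_per_sea=60, seed=300 + seed),
                truth,
                cohorts=(COHORT_CHILD,),
            )
            t = ls.survey_table(hh, ind)
            part = t[t["participated"] == 1]
            out = ls.build_design(part, ls.ModelSpec.child_outcome())
            sel = ls.build_design(t, ls.ModelSpec.child_selection())
            ols_est.append(ls.fit_ols(out).params["log_distance"])
            heck_est.append(ls.fit_heckman_two_step(out, sel).second_stage.params["log_distance"])
        bias_ols = abs(np.mean(ols_est) - (-0.755))
        bias_heck = abs(np.mean(heck_est) - (-0.755))
        assert bias_heck < bias_ols


class TestGroupComparison:
    def test_identical_groups(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0] * 2, "participated": [1, 1, 1, 0, 0, 0]})
        t, p = ls.compare_groups(df, "v")
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_welch_t(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0, 2.0, 3.0, 4.0], "participated": [1, 1, 1, 0, 0, 0]})
        t, p = ls.compare_groups(df, "v")
        # means 2 and 3, each variance 1 with n=3: t = -1 / sqrt(2/3)
        expect_t = -1.0 / math.sqrt(2.0 / 3.0)
        assert t == pytest.approx(expect_t, rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(expect_t), df=4), rel=1e-9)

    def test_zero_variance_everywhere_is_undefined(self):
        df = pd.DataFrame({"v": [1.0, 1.0, 2.0, 2.0], "participated": [1, 1, 0, 0]})
        with pytest.raises(UndefinedStatisticError):
            ls.compare_groups(df, "v")

    def test_location_shift_in_selection_shows_in_balance_table(self):
        # tilt participation towards the informal settlement: the balance
        # diagnostic should flag the share difference in most replicates
        truth = ls.TruthParams()
        truth.delta_child["makululu"] = 0.4
        hits = 0
        for seed in range(11):
            hh, ind = ls.generate_survey(
                SamplingConfig(seed=600 + seed), truth, cohorts=(COHORT_CHILD,)
            )
            t = ls.survey_table(hh, ind)
            t["makululu"] = (t["location_class"] == "makululu").astype(float)
            _, p = ls.compare_groups(t, "makululu")
            hits += p < 0.10
        assert hits > 5

    def test_participation_balance_shape(self, survey_frame):
        child = survey_frame[survey_frame["cohort"] == COHORT_CHILD]
        child = child.assign(window=child["window_days"])
        table = ls.participation_balance(child, ["age_years", "household_size"])
        assert list(table.index) == ["age_years", "household_size"]
        assert ((table["p_value"] >= 0) & (table["p_value"] <= 1)).all()
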