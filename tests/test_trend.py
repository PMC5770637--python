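"""Trend model: response prep, outlier rule, spline basis, GLMM fits, AIC."""

import numpy as np
import pandas as pd
import pytest

import statsmodels.api as sm
from scipy import stats

from pulse15n._gamma_glmm import (
    build_glmm_data,
    fit_gamma_glmm,
    marginal_loglik,
    sd_resid_to_shape,
    shape_to_sd_resid,
)
from pulse15n.simulate import simulate_enrichment_glmm, trend_design
from pulse15n.trend import (
    TimeSplineBasis,
    TrendModelSpec,
    akaike_weights,
    build_time_basis,
    fit_gamma_gamm,
    prepare_response,
    remove_outliers,
)


class TestResponsePreparation:
    def test_offset_applied(self):
        out = prepare_response([0.0, 746.60])
        assert out[0] == pytest.approx(0.001)
        assert out[1] == pytest.approx(746.601)

    def test_negative_beyond_offset_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            prepare_response([-0.002])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            prepare_response([np.nan])


class TestOutlierRemoval:
    @staticmethod
    def frame(values, comp="moss"):
        return pd.DataFrame({"compartment": comp, "enrichment": values})

    def test_no_extremes_identity(self, rng):
        df = self.frame(rng.normal(10, 1, 200))
        kept, report = remove_outliers(df)
        assert len(kept) == 200 and report.empty

    def test_planted_extreme_removed(self, rng):
        vals = rng.normal(10, 1, 499).tolist() + [500.0]
        kept, report = remove_outliers(self.frame(vals))
        assert len(report) == 1
        assert report["enrichment"].iloc[0] == 500.0
        assert 500.0 not in kept["enrichment"].values

    def test_cap_limits_removal(self, rng):
        vals = np.r_[rng.normal(10, 1, 450), rng.uniform(200, 400, 50)]
        with pytest.warns(UserWarning, match="cap"):
            kept, report = remove_outliers(self.frame(vals), max_fraction=0.02)
        assert len(report) == 10  # 2% of 500
        # worst points go first
        assert report["enrichment"].min() >= np.sort(vals)[-10]

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            remove_outliers(self.frame([1.0]), max_fraction=0.2)


def deboor(knots, degree, i, x):
    """Textbook Cox–de Boor recursion (independent of scipy)."""
    if degree == 0:
        return 1.0 if knots[i] <= x < knots[i + 1] else 0.0
    left, right = 0.0, 0.0
    den1 = knots[i + degree] - knots[i]
    if den1 > 0:
        left = (x - knots[i]) / den1 * deboor(knots, degree - 1, i, x)
    den2 = knots[i + degree + 1] - knots[i + 1]
    if den2 > 0:
        right = (knots[i + degree + 1] - x) / den2 * deboor(knots, degree - 1, i + 1, x)
    return left + right


class TestSplineBasis:
    def test_df4_on_nine_years_gives_four_centered_columns(self):
        times = np.arange(9.0)
        B, basis = build_time_basis(times, df=4)
        assert B.shape == (9, 4)
        assert np.allclose(B.mean(axis=0), 0.0, atol=1e-12)

    def test_matches_de_boor_recursion(self):
        times = np.arange(9.0)
        basis = TimeSplineBasis(df=5).fit(times)
        raw = basis.raw(times)
        xs = np.linspace(0.0, 8.0, 33)[:-1]  # right boundary has a different convention
        for j in range(raw.shape[1]):
            hand = [deboor(basis.knots, 3, j, x) for x in xs]
            assert np.allclose(basis.raw(xs)[:, j], hand, atol=1e-10)

    def test_df3_with_intercept_spans_cubics(self):
        times = np.linspace(0, 8, 30)
        B, _ = build_time_basis(times, df=3)
        X = np.column_stack([np.ones_like(times), B])
        target = 2.0 - 1.5 * times + 0.3 * times**2 - 0.02 * times**3
        coef, res, *_ = np.linalg.lstsq(X, target, rcond=None)
        assert np.allclose(X @ coef, target, atol=1e-9)

    def test_insufficient_distinct_times_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            build_time_basis([0.0, 1.0, 2.0, 2.0], df=4)
        with pytest.raises(ValueError, match="df"):
            build_time_basis(np.arange(9.0), df=2)


class TestGlmmEngine:
    @staticmethod
    def small_dataset(seed=0, sd_plot=0.0, rho=0.0, n_plots=6):
        rng = np.random.default_rng(seed)
        design = trend_design(n_plots=n_plots, times=tuple(range(6)),
                              compartments=("above_ground_biomass", "moss"))
        return simulate_enrichment_glmm(
            design, intercept=3.0, contrasts={"moss": 1.0}, smooth=None,
            sd_plot=sd_plot, sd_resid=0.45, rho=rho, rng=rng,
        )

    def test_reduced_model_matches_independent_gamma_glm(self):
        """With both variance components off, the fit is a gamma GLM; the
        coefficients must agree with statsmodels IRLS to 1e-6."""
        data = self.small_dataset(seed=4)
        spec = TrendModelSpec(
            fixed_terms="compartment_only", estimate_plot_sd=False, estimate_rho=False
        )
        fit = fit_gamma_gamm(data, spec)
        X = np.column_stack(
            [np.ones(len(data)), (data["compartment"] == "moss").to_numpy(float)]
        )
        y = data["enrichment"].to_numpy() + spec.response_offset
        glm = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log())).fit()
        assert np.allclose(fit.fit.beta, glm.params, atol=1e-6)

    def test_quadrature_matches_independent_trapezoid_integration(self):
        """Gauss–Hermite marginal likelihood vs a brute-force trapezoid
        integral of gamma-density × copula × normal density."""
        data = self.small_dataset(seed=8, sd_plot=0.3, rho=0.4)
        X = np.column_stack(
            [np.ones(len(data)), (data["compartment"] == "moss").to_numpy(float)]
        )
        y = data["enrichment"].to_numpy()
        gd = build_glmm_data(data[["plot", "time", "compartment"]], X, y)
        beta = np.array([3.0, 1.0])
        k, sigma_b, rho = 5.0, 0.3, 0.4
        ll_gh = marginal_loglik(beta, np.log(k), np.log(sigma_b), np.arctanh(rho), gd, n_quad=40)

        # independent route: loop over plots, trapezoid over b
        df = data.copy()
        df["eta"] = 3.0 + (df["compartment"] == "moss") * 1.0
        bs = np.linspace(-8 * sigma_b, 8 * sigma_b, 4001)
        ll_trap = 0.0
        for _, plot_df in df.groupby("plot"):
            vals = []
            for b in bs:
                cond = 0.0
                for _, series in plot_df.groupby("compartment"):
                    series = series.sort_values("time")
                    mu = np.exp(series["eta"].to_numpy() + b)
                    yv = series["enrichment"].to_numpy()
                    cond += stats.gamma.logpdf(yv, a=k, scale=mu / k).sum()
                    u = np.clip(stats.gamma.cdf(yv, a=k, scale=mu / k), 1e-12, 1 - 1e-12)
                    z = stats.norm.ppf(u)
                    for t in range(1, len(z)):
                        cond += (
                            stats.norm.logpdf(z[t], loc=rho * z[t - 1],
                                              scale=np.sqrt(1 - rho**2))
                            - stats.norm.logpdf(z[t])
                        )
                vals.append(cond + stats.norm.logpdf(b, scale=sigma_b))
            m = np.max(vals)
            ll_trap += m + np.log(np.trapezoid(np.exp(np.array(vals) - m), bs))
        assert ll_gh == pytest.approx(ll_trap, abs=1e-6)

    def test_fit_deterministic(self):
        data = self.small_dataset(seed=3, sd_plot=0.2, rho=0.2)
        spec = TrendModelSpec(fixed_terms="compartment_only")
        f1 = fit_gamma_gamm(data, spec)
        f2 = fit_gamma_gamm(data, spec)
        assert np.array_equal(f1.fit.beta, f2.fit.beta)
        assert f1.loglik == f2.loglik

    def test_variance_components_shrink_with_n_under_null(self):
        """With sigma_b = rho = 0 in truth, |rho| estimates decrease with n
        and sigma_b estimates stay within a parametric-rate envelope of 0
        (boundary piling makes the raw sigma_b median non-monotone)."""
        sizes = {63: 7, 315: 35, 630: 70}  # n_obs: plots of 9 obs each
        med_rho, med_sb = [], []
        for n_obs, n_plots in sizes.items():
            rhos, sbs = [], []
            for rep in range(7):
                rng = np.random.default_rng(100 + rep)
                design = trend_design(n_plots=n_plots, times=tuple(range(9)),
                                      compartments=("above_ground_biomass",))
                data = simulate_enrichment_glmm(
                    design, intercept=3.0, contrasts=None, smooth=None,
                    sd_plot=0.0, sd_resid=0.45, rho=0.0, rng=rng,
                )
                fit = fit_gamma_gamm(data, TrendModelSpec(fixed_terms="time_only"))
                rhos.append(abs(fit.rho))
                sbs.append(fit.sd_plot)
            med_rho.append(np.median(rhos))
            med_sb.append(np.median(sbs))
        assert med_rho[0] >= med_rho[1] >= med_rho[2]
        for med, (n_obs, n_plots) in zip(med_sb, sizes.items()):
            assert med <= 0.3 / np.sqrt(n_plots)

    def test_shape_sd_resid_roundtrip(self):
        for sd in (0.1, 0.439, 1.2):
            assert shape_to_sd_resid(sd_resid_to_shape(sd)) == pytest.approx(sd, rel=1e-10)

    def test_flat_truth_gives_null_smooth(self):
        """Single compartment, no time effect: the fitted smooth stays within
        its own 95% band of zero."""
        rng = np.random.default_rng(17)
        design = trend_design(n_plots=7, times=tuple(range(9)),
                              compartments=("above_ground_biomass",))
        data = simulate_enrichment_glmm(
            design, intercept=3.0, contrasts=None, smooth=None,
            sd_plot=0.2, sd_resid=0.45, rho=0.2, rng=rng,
        )
        fit = fit_gamma_gamm(data, TrendModelSpec(fixed_terms="time_only"))
        cov = fit.fit.covariance()
        curve = fit.smooth_curve(covariance=cov)
        assert ((curve["lower_95"] <= 0) & (curve["upper_95"] >= 0)).mean() > 0.8


class TestModelSelection:
    def test_akaike_weights_normalized_and_shift_invariant(self, rng):
        aics = rng.uniform(100, 200, 6)
        w = akaike_weights(aics)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(akaike_weights(aics + 57.0), w)

    def test_identical_candidates_split_evenly(self):
        w = akaike_weights([123.4, 123.4])
        assert np.allclose(w, [0.5, 0.5])

    def test_no_time_effect_prefers_compartment_only(self):
        """Simulation oracle: with a flat time truth, the compartment-only
        model beats the additive one in most replicates (AIC parsimony)."""
        wins = 0
        n_rep = 8
        for rep in range(n_rep):
            rng = np.random.default_rng(300 + rep)
            data = simulate_enrichment_glmm(
                trend_design(n_plots=7, times=tuple(range(9)),
                             compartments=("above_ground_biomass", "moss", "O_horizon")),
                intercept=3.0, contrasts={"moss": 1.0, "O_horizon": -0.5},
                smooth=None, sd_plot=0.2, sd_resid=0.45, rho=0.2, rng=rng,
            )
            f_comp = fit_gamma_gamm(data, TrendModelSpec(fixed_terms="compartment_only"))
            f_add = fit_gamma_gamm(data, TrendModelSpec(fixed_terms="additive"))
            wins += int(f_comp.aic < f_add.aic)
        assert wins >= n_rep * 0.6
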