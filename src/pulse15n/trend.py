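"""Temporal trend models for ¹⁵N enrichment: gamma log-link GAMM with
plot random intercept and AR-1 residual correlation.

The enrichment response is strictly positive after a small offset, strongly
right-skewed, and measured repeatedly on the same plots — hence a gamma
distribution with a log link, a plot-level random intercept, and first-order
autocorrelation of residuals within each plot's time series.  The time effect
is a cubic regression spline with a small, fixed number of degrees of freedom
(default 4), which keeps the model parametric: no smoothing-parameter
selection is involved.  Candidate fixed-effect structures (time only,
compartment only, additive, interaction) are compared by AIC under maximum
likelihood; the selected model is refit with a restricted-likelihood
adjustment for reporting.

Compartments enter at the level the trend analysis uses: above-ground
biomass, moss, and the O-, A- and B-horizons, with above-ground biomass as
the baseline for contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from ._gamma_glmm import (
    ConvergenceError,
    GlmmFit,
    build_glmm_data,
    fit_gamma_glmm,
    sd_resid_to_shape,
    shape_to_sd_resid,
)

__all__ = [
    "trend_dataset_from_measurements",
    "TREND_COMPARTMENTS",
    "FIXED_TERMS",
    "TrendModelSpec",
    "TrendFit",
    "TimeSplineBasis",
    "prepare_response",
    "remove_outliers",
    "build_time_basis",
    "fit_gamma_gamm",
    "akaike_weights",
    "select_model",
]

#: Compartment strata used by the trend analysis (baseline first).
TREND_COMPARTMENTS = ("above_ground_biomass", "moss", "O_horizon", "A_horizon", "B_horizon")

FIXED_TERMS = ("time_only", "compartment_only", "additive", "interaction")


#: Sampled compartments folded into the above-ground biomass stratum.
_BIOMASS_MEMBERS = ("current_year_shoots", "shoots_1_2yr", "litter_current")


def trend_dataset_from_measurements(measurements: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a paired measurement table into the five trend strata.

    Per plot and year the enrichment of the above-ground biomass stratum is
    the mean over its member compartments (current-year shoots, 1–2-year
    shoots, current-year litter); moss and the three soil horizons map one to
    one.  Time is years since the first sampling occasion.
    """
    from .recovery import pair_measurements

    paired = pair_measurements(measurements)
    from . import isotopes

    paired = paired.assign(
        enrichment=isotopes.enrichment(
            paired["delta_lab"].to_numpy(), paired["delta_ref"].to_numpy()
        )
    )
    mapping = {m: "above_ground_biomass" for m in _BIOMASS_MEMBERS}
    for c in ("moss", "O_horizon", "A_horizon", "B_horizon"):
        mapping[c] = c
    paired = paired[paired["compartment"].isin(mapping)]
    paired = paired.assign(compartment=paired["compartment"].map(mapping))
    agg = (
        paired.groupby(["plot", "year", "compartment"], as_index=False)["enrichment"]
        .mean()
    )
    agg["time"] = agg["year"] - agg["year"].min()
    return agg[["plot", "time", "year", "compartment", "enrichment"]]


# --------------------------------------------------------------------------
# response preparation


def prepare_response(values, offset: float = 0.001) -> np.ndarray:
    """Shift enrichment values by a small positive offset for the gamma fit.

    The offset (default 0.001 ‰) keeps structural zeros inside the gamma
    support; any value that remains non-positive is an error, reported with
    its position.
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("enrichment values must be finite")
    out = v + offset
    bad = np.flatnonzero(out <= 0)
    if len(bad):
        raise ValueError(
            f"{len(bad)} enrichment value(s) non-positive after offset "
            f"(indices {bad[:10].tolist()}{'...' if len(bad) > 10 else ''})"
        )
    return out


def remove_outliers(
    data: pd.DataFrame,
    value_column: str = "enrichment",
    group_column: str | None = "compartment",
    max_fraction: float = 0.02,
    iqr_factor: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag and drop extreme values beyond Q3 + 3·IQR (or Q1 − 3·IQR).

    Fences are computed within ``group_column`` (compartments have wildly
    different enrichment scales).  At most ``max_fraction`` of all points are
    removed, most extreme first; the returned report lists every removal with
    its exceedance distance.
    """
    if not 0 <= max_fraction <= 0.05:
        raise ValueError("max_fraction must lie in [0, 0.05]")
    df = data.reset_index(drop=True)
    groups = df.groupby(group_column) if group_column else [(None, df)]
    excess = pd.Series(0.0, index=df.index)
    for _, grp in groups:
        v = grp[value_column]
        q1, q3 = v.quantile(0.25), v.quantile(0.75)
        iqr = q3 - q1
        hi, lo = q3 + iqr_factor * iqr, q1 - iqr_factor * iqr
        exc = np.maximum(v - hi, lo - v)
        excess.loc[grp.index] = exc
    flagged = excess[excess > 0].sort_values(ascending=False)
    n_max = int(np.floor(max_fraction * len(df)))
    if len(flagged) > n_max:
        warnings.warn(
            f"{len(flagged)} points beyond the outlier fence but cap allows "
            f"removing only {n_max}; keeping the least extreme ones",
            stacklevel=2,
        )
    drop_idx = flagged.index[:n_max]
    report = df.loc[drop_idx].copy()
    report["fence_exceedance"] = excess.loc[drop_idx]
    retained = df.drop(index=drop_idx).reset_index(drop=True)
    return retained, report.reset_index(drop=True)


# --------------------------------------------------------------------------
# spline basis


@dataclass
class TimeSplineBasis:
    """Cubic regression spline basis with quantile interior knots.

    ``df`` columns after the identifiability constraint: the raw cubic
    B-spline basis has df+1 functions (df−3 interior knots at quantiles of
    the observed times, clamped boundary knots at the observed range); its
    columns are centered on the observed times and one redundant column is
    dropped, so the span excludes the constant and the basis can sit next to
    an intercept.
    """

    df: int = 4
    knots: np.ndarray | None = None
    column_means: np.ndarray | None = None

    def fit(self, times) -> "TimeSplineBasis":
        t = np.unique(np.asarray(times, dtype=float))
        if self.df < 3:
            raise ValueError("a cubic regression spline needs df >= 3")
        if len(t) < self.df + 1:
            raise ValueError(
                f"need at least df+1={self.df + 1} distinct time points, got {len(t)}"
            )
        n_interior = self.df - 3
        if n_interior:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(t, qs)
        else:
            interior = np.array([])
        lo, hi = t.min(), t.max()
        self.knots = np.r_[[lo] * 4, interior, [hi] * 4]
        raw = self.raw(np.asarray(times, dtype=float))
        self.column_means = raw.mean(axis=0)
        return self

    def raw(self, times) -> np.ndarray:
        """Uncentered df+1 B-spline columns (clamped to the fitted range)."""
        if self.knots is None:
            raise RuntimeError("basis not fitted")
        x = np.clip(np.asarray(times, dtype=float), self.knots[0], self.knots[-1])
        return BSpline.design_matrix(x, self.knots, 3).toarray()

    def transform(self, times) -> np.ndarray:
        """Centered basis with the last column dropped: the df model columns."""
        if self.column_means is None:
            raise RuntimeError("basis not fitted")
        centered = self.raw(times) - self.column_means
        return centered[:, :-1]

    @property
    def column_names(self) -> list[str]:
        return [f"s(time).{i + 1}" for i in range(self.df)]


def build_time_basis(times, df: int = 4) -> tuple[np.ndarray, TimeSplineBasis]:
    """Convenience wrapper: fit a :class:`TimeSplineBasis` and return its columns."""
    basis = TimeSplineBasis(df=df).fit(times)
    return basis.transform(times), basis


# --------------------------------------------------------------------------
# model specification and design


@dataclass(frozen=True)
class TrendModelSpec:
    """Specification of one candidate gamma GAMM."""

    fixed_terms: str = "additive"
    spline_df: int = 4
    response_offset: float = 0.001
    baseline: str = "above_ground_biomass"
    estimate_plot_sd: bool = True
    estimate_rho: bool = True
    n_quad: int = 9

    def __post_init__(self):
        if self.fixed_terms not in FIXED_TERMS:
            raise ValueError(f"fixed_terms must be one of {FIXED_TERMS}")
        if self.response_offset <= 0:
            raise ValueError("response_offset must be positive")
        if self.spline_df < 2:
            raise ValueError("spline_df must be at least 2")


def _design(
    data: pd.DataFrame, spec: TrendModelSpec, basis: TimeSplineBasis | None = None
) -> tuple[np.ndarray, list[str], TimeSplineBasis | None, list[str]]:
    comps = [c for c in dict.fromkeys(data["compartment"])]
    if spec.baseline in comps:
        levels = [spec.baseline] + sorted(c for c in comps if c != spec.baseline)
    else:
        levels = sorted(comps)
    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]

    use_comp = spec.fixed_terms in ("compartment_only", "additive", "interaction")
    use_time = spec.fixed_terms in ("time_only", "additive", "interaction")

    if use_comp and len(levels) > 1:
        for lev in levels[1:]:
            cols.append((data["compartment"] == lev).to_numpy(dtype=float))
            names.append(f"compartment[{lev}]")

    if use_time:
        if basis is None:
            basis = TimeSplineBasis(df=spec.spline_df).fit(data["time"])
        S = basis.transform(data["time"])
        if spec.fixed_terms == "interaction":
            for lev in levels:
                ind = (data["compartment"] == lev).to_numpy(dtype=float)
                for j in range(S.shape[1]):
                    cols.append(S[:, j] * ind)
                    names.append(f"s(time).{j + 1}:compartment[{lev}]")
        else:
            for j in range(S.shape[1]):
                cols.append(S[:, j])
                names.append(f"s(time).{j + 1}")
    return np.column_stack(cols), names, basis, levels


# --------------------------------------------------------------------------
# fitting


@dataclass
class TrendFit:
    """A fitted candidate model with everything reporting needs."""

    spec: TrendModelSpec
    fit: GlmmFit
    basis: TimeSplineBasis | None
    levels: list[str]
    delta_aic: float = np.nan
    akaike_weight: float = np.nan

    @property
    def coefficients(self) -> pd.Series:
        return self.fit.coefficients

    @property
    def sd_plot(self) -> float:
        return self.fit.sigma_b

    @property
    def sd_resid(self) -> float:
        return self.fit.sd_resid

    @property
    def rho(self) -> float:
        return self.fit.rho

    @property
    def loglik(self) -> float:
        return self.fit.loglik

    @property
    def aic(self) -> float:
        return self.fit.aic

    def adjusted_r2(self) -> float:
        """Approximate link-scale adjusted R² against the intercept-only model."""
        y = np.log(self.fit.data.y)
        eta = self.fit.data.X @ self.fit.beta
        rss = float(np.sum((y - eta) ** 2))
        tss = float(np.sum((y - y.mean()) ** 2))
        n, p = len(y), len(self.fit.beta)
        if n - p - 1 <= 0 or tss == 0:
            return np.nan
        return 1.0 - (rss / tss) * (n - 1) / (n - p - 1)

    def smooth_curve(
        self, times=None, compartment: str | None = None, covariance: pd.DataFrame | None = None
    ) -> pd.DataFrame:
        """Evaluate the fitted time smooth (link scale) on a grid.

        For the interaction model, ``compartment`` selects whose smooth to
        evaluate.  If a coefficient covariance (from ``fit.covariance()``) is
        passed, a pointwise 95% confidence band is attached.
        """
        if self.basis is None:
            raise ValueError("this candidate has no time term")
        if times is None:
            times = np.linspace(self.basis.knots[0], self.basis.knots[-1], 101)
        S = self.basis.transform(times)
        if self.spec.fixed_terms == "interaction":
            if compartment is None:
                raise ValueError("interaction model: specify the compartment")
            cols = [f"s(time).{j + 1}:compartment[{compartment}]" for j in range(S.shape[1])]
        else:
            cols = [f"s(time).{j + 1}" for j in range(S.shape[1])]
        idx = [list(self.fit.columns).index(c) for c in cols]
        coef = self.fit.beta[idx]
        effect = S @ coef
        out = pd.DataFrame({"time": np.asarray(times, dtype=float), "effect": effect})
        if covariance is not None:
            V = covariance.loc[cols, cols].to_numpy()
            se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", S, V, S), 0.0))
            out["lower_95"] = effect - 1.96 * se
            out["upper_95"] = effect + 1.96 * se
        return out


def fit_gamma_gamm(
    data: pd.DataFrame,
    spec: TrendModelSpec | None = None,
    method: str = "ML",
    start: dict | None = None,
) -> TrendFit:
    """Fit one candidate gamma GAMM.

    ``data`` needs columns plot, time, compartment and enrichment.  The
    response offset, fixed-effect structure, spline df and variance
    components all come from ``spec``.  Deterministic given data and
    starting values.
    """
    spec = spec or TrendModelSpec()
    for col in ("plot", "time", "compartment", "enrichment"):
        if col not in data.columns:
            raise ValueError(f"trend data lacks column {col!r}")
    y = prepare_response(data["enrichment"].to_numpy(), spec.response_offset)
    X, names, basis, levels = _design(data, spec)
    glmm_data = build_glmm_data(
        data[["plot", "time", "compartment"]],
        X,
        y,
        columns=tuple(names),
    )
    fit = fit_gamma_glmm(
        glmm_data,
        method=method,
        estimate_sigma_b=spec.estimate_plot_sd,
        estimate_rho=spec.estimate_rho,
        n_quad=spec.n_quad,
        start=start,
    )
    return TrendFit(spec=spec, fit=fit, basis=basis, levels=levels)


def akaike_weights(aics) -> np.ndarray:
    """exp(−Δ/2) normalized; invariant to adding a constant to all AICs."""
    a = np.asarray(aics, dtype=float)
    d = a - np.nanmin(a)
    w = np.exp(-0.5 * d)
    return w / np.nansum(w)


def select_model(
    data: pd.DataFrame,
    candidates=FIXED_TERMS,
    base_spec: TrendModelSpec | None = None,
    refit_best: bool = True,
) -> tuple[pd.DataFrame, list[TrendFit], TrendFit | None]:
    """AIC model selection over candidate fixed-effect structures.

    All candidates are fitted by maximum likelihood; the summary frame ranks
    them by ΔAIC with Akaike weights.  Non-convergent candidates are excluded
    with a warning and the weights renormalized.  The best model is refit
    with the restricted-likelihood adjustment for reporting.
    """
    base_spec = base_spec or TrendModelSpec()
    if len(candidates) < 2:
        raise ValueError("need at least two candidate models")
    fits: list[TrendFit] = []
    for cand in candidates:
        spec = replace(base_spec, fixed_terms=cand)
        try:
            fits.append(fit_gamma_gamm(data, spec, method="ML"))
        except ConvergenceError as err:
            warnings.warn(f"candidate {cand!r} excluded (non-convergent): {err}", stacklevel=2)
    if not fits:
        raise ConvergenceError("no candidate model converged")
    aics = np.array([f.aic for f in fits])
    weights = akaike_weights(aics)
    best_aic = aics.min()
    for f, w in zip(fits, weights):
        f.delta_aic = f.aic - best_aic
        f.akaike_weight = float(w)
    order = np.argsort(aics)
    fits = [fits[i] for i in order]
    summary = pd.DataFrame(
        {
            "model": [f.spec.fixed_terms for f in fits],
            "n_params": [f.fit.n_params for f in fits],
            "loglik": [f.loglik for f in fits],
            "AIC": [f.aic for f in fits],
            "delta_AIC": [f.delta_aic for f in fits],
            "akaike_weight": [f.akaike_weight for f in fits],
            "adj_R2": [f.adjusted_r2() for f in fits],
        }
    )
    best_reml = None
    if refit_best:
        best = fits[0]
        best_reml = fit_gamma_gamm(
            data,
            best.spec,
            method="REML",
            start={
                "beta": best.fit.beta,
                "shape": best.fit.shape,
                "sigma_b": max(best.fit.sigma_b, 1e-3),
                "rho": best.fit.rho,
            },
        )
        best_reml.delta_aic = 0.0
        best_reml.akaike_weight = best.akaike_weight
    return summary, fits, best_reml
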