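# Methods

This note records the models, conventions and numerical choices behind
`pulse15n`, and what the synthetic-data checks do and do not establish.

## Isotope conventions

All δ values are per-mil deviations of the ¹⁵N/¹⁴N ratio from atmospheric
N₂.  The standard ratio defaults to R_std = 0.0036765 (the conventional
air-N₂ value) and is configurable everywhere it enters; enrichment,
being a ratio of δ differences, is independent of it.  δ, ratio and atom
fraction are carried at full floating precision; rounding to two decimals
happens only in report writers.  δ ≤ −1000 ‰ (zero or negative ¹⁵N) is
rejected as non-physical.

**Tracer-dose bookkeeping.**  The applied dose is a mass of double-labelled
ammonium nitrate; its N content follows from the molar mass computed at the
stated label atom fraction (both N positions labelled).  The quantity used
as the recovery denominator is the *excess* ¹⁵N above the reference
abundance, N_mass · (at.%_label − at.%_ref)/100.  The per-compartment
recovery formula m_pool·(at.%_pool − at.%_ref)/(at.%_tracer − at.%_ref)
shares this excess structure, so "100 % recovery" means exactly that the
whole applied excess is found in the measured pools; a gross-¹⁵N
denominator (without the −at.%_ref) differs by a constant factor of about
0.996 at 98 at.% label and is available by passing the label atom percent
as the reference-free denominator.  Absolute gram values inherit the
excess convention; every published comparison in this package is on the
percent scale, where the convention cancels.

**Reference abundance per cell.**  The reference atom fraction for a
labelled sample is taken from the paired reference subplot of the same
plot, year and compartment; when that pair is missing, the compartment ×
year mean of the reference subplots is substituted (and the strict mode
raises instead).  This mirrors the paired-subplot field design.

## Aggregation of enrichment

Two aggregation modes exist because they answer slightly different
questions and published tables mix them: `per_plot_mean` applies the
enrichment formula within each plot pair and averages over plots (SE =
SD/√n over plots; the default), while `mean_of_deltas` applies the formula
to the group-mean δ values.  The two coincide exactly when all plots share
the same reference δ, and differ by a Jensen-type term otherwise.  Years in
which a compartment was not sampled are omitted, never imputed, so annual
totals change composition across years exactly as sampled.

## Flow inference

The flow ledger solves per-edge tracer flows from per-compartment changes
in % recovery over an interval.  The topology is a small directed graph
(default: atmosphere→moss for the pulse; moss→O; moss→loss as the residual;
O→A→B→leachate; O→plants→litter→O) plus exogenous, observable fluxes
(plant-to-litter transfer, leachate export).  The solver repeatedly finds
an internal node with exactly one undetermined incident edge and closes its
balance inflow − outflow = Δ; if no such node exists the system is not
single-pass identifiable and an explicit error is raised.  Consequences of
this construction:

- every node balance closes to machine precision, hence global
  conservation: Σ Δ + residual + leachate − pulse = 0;
- the solution is linear in the Δ vector (superposition holds);
- negative solved flows are reported with a warning, never clamped — a
  negative O→A flow represents upward transport (bioturbation), a negative
  residual apparent tracer creation from measurement noise.

The partition between plant uptake and litter return is not identifiable
from recovery data alone; the resolution order above is one consistent
choice and the litter flux enters as an input where it has been measured.

## The gamma GAMM

Enrichment is strictly positive after a small offset (0.001 ‰, added to
keep structural zeros inside the gamma support), strongly right-skewed and
heteroscedastic, hence a gamma distribution with log link.  The model is

EN_ij ~ Gamma(mean μ_ij = exp(α + f(t_ij) + β·comp_ij + b_i), shape k),

with b_i ~ N(0, σ_b²) a plot random intercept.  Serial dependence within
each plot × compartment time series is a Gaussian copula on the conditional
gamma quantiles whose normal scores follow an AR-1 process with correlation
ρ.  This makes "AR-1 residuals" a proper likelihood statement: with σ_b = 0
and ρ = 0 the model collapses exactly to a gamma GLM.  The reported
residual SD is the link-scale value √trigamma(k) = SD(log Y | b).

**Spline.**  f is a cubic regression spline with fixed degrees of freedom
(default 4, no penalization — with df stated in advance there is no
smoothing parameter to select, and the model stays parametric).  The raw
basis has df+1 cubic B-spline functions with df−3 interior knots at
quantiles of the observed times and clamped boundary knots; columns are
centered over the observed times and one redundant column dropped, so the
span excludes the constant and the basis coexists with an intercept.  A
cubic basis needs df ≥ 3; the default design (9 annual occasions, df = 4)
gives 4 centered columns.  In the interaction model each compartment gets
its own smooth (spline ⊗ compartment indicators); note that the centering
then reallocates part of each compartment's mean level between its contrast
and its smooth, so contrasts are comparable only within a parameterization.

**Estimation.**  The random intercept is integrated out by Gauss–Hermite
quadrature (9 nodes by default; the integrand is smooth and
one-dimensional per plot), and all parameters (β, log k, log σ_b,
atanh ρ) are maximized jointly with L-BFGS-B, warm-started from a gamma GLM
fit.  Quantiles are clipped to [1e-12, 1−1e-12] before the normal-score
transform; this clipping is part of the copula-likelihood definition.
Fits are deterministic given data and starting values; non-convergence
raises a diagnostic error carrying the optimizer trace (model selection
excludes such candidates with a warning and renormalizes the weights).

**Restricted likelihood.**  The reporting refit uses a Cox–Reid adjusted
profile likelihood.  For a gamma log-link model the GLM working information
for β is k·XᵀX, so the adjustment reduces to an extra −½·p·log k on the
log-likelihood (the constant log det XᵀX does not affect the optimum).
This is a likelihood-level definition chosen here; mixed-model software
implements REML for this model class in package-specific ways and exact
numerical agreement with any particular one is not claimed.

**Model selection.**  Candidates (time only, compartment only, additive,
interaction) are fitted by ML; Akaike weights are w_i = exp(−Δ_i/2)/Σ
exp(−Δ_j/2).  The adjusted R² is computed on the link scale against the
intercept-only model and is approximate by construction.

**Outliers.**  The rule "flag beyond Q3 + 3·IQR (or below Q1 − 3·IQR)
within compartment, remove at most 2 % of all points, most extreme first,
with a written report" operationalizes visual dot-plot screening in a
reproducible way; the fences are computed per compartment because
enrichment scales differ by orders of magnitude between moss and the
B-horizon.

## Synthetic data: what it emulates and what it does not

The tracer-fate simulator uses annual discrete time (sampling was annual;
sub-annual dynamics are not identifiable from annual data, so a
continuous-time variant was rejected).  A configurable share of the pulse
(default 0.66) is retained by the moss at application; the rest is split
over soil horizons, shoots, litter and an immediate loss (defaults chosen
once so that the simulated trajectories qualitatively match the published
pattern: moss falling from ~66 % to the mid-teens within four annual
steps, the O-horizon climbing toward ~40 % by year 8).  Each year every
compartment exports fixed first-order fractions of its stock along the
default topology; per-plot lognormal jitter (SD 0.25 on the log scale) on
the rates creates between-plot variation, and Gaussian noise (SD 1 ‰,
the order of between-sample IRMS spread in reference subplots) is added on
the δ scale — measurement-level, because IRMS error is δ-scale, not
mass-scale.  Natural-abundance baselines per compartment are set to
realistic values (plant material ≈ −6 to −7 ‰, soil increasingly positive
with depth).  Pool masses are plausible synthetic values for a dwarf-shrub
heath on podzol, not taken from any published pool table.

The simulator conserves mass exactly and the measurement generator
inverts the recovery formula exactly, so noise-free pipeline inversion is a
machine-precision identity.  What passing these checks shows: the
arithmetic, pairing, aggregation and mass-balance logic are internally
consistent and unbiased under the stated generative model.  What they do
not show: that real field data satisfy first-order annual kinetics,
lognormal rate variation or δ-scale Gaussian noise; real moss/soil
exchange is pulse-driven by rain events, microbial immobilization is not
mechanistic here, and no weather forcing exists.

The enrichment generator draws from exactly the model the fitter
maximizes (normal plot intercepts, AR-1 copula, gamma marginals), which is
what makes the parameter-recovery study a pure test of the estimation
machinery: at the field design size the mean refitted intercept over 200
replicates sits within two Monte-Carlo standard errors of the simulation
truth, and with genuinely compartment-specific trends the interaction
model attains Akaike weight ≈ 1 in essentially all replicates.

## Problem sizes and numerical tolerances

Replicate studies run at the field design size (7 plots × 9 occasions × 5
strata, n = 315): 200 replicates for intercept recovery, 100 for model
selection — enough for Monte-Carlo SEs an order of magnitude below the
effects of interest while keeping a full run in minutes on one CPU.
Roundtrip identities are asserted at 1e-12 relative, conservation and
pipeline inversion at 1e-9, quadrature-vs-brute-force likelihood agreement
at 1e-6, and the reduced-model (gamma GLM) coefficient agreement at 1e-6.

## Known limitations

- Recovery uncertainty is plot-to-plot SE only; no error propagation from
  pool-mass uncertainty (pool masses enter as fixed inputs).
- The flow ledger gives point flows; no statistical uncertainty is attached.
- The REML-analogue is a Cox–Reid adjustment, not a reimplementation of any
  specific mixed-model package's REML.
- The adjusted R² is a link-scale approximation.
- Multiple-testing correction is deliberately absent from the paired
  t-tests (one test per compartment × year, reported as such).
- Leachate enters pool accounting and the ledger as measured fluxes; the
  chemistry of leachate δ¹⁵N determination is out of scope.

The importable API plus the `examples/` scripts are the primary interface;
the `pulse15n` CLI is a thin convenience wrapper over the same functions.
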