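"""Gamma GAMM model selection on simulated enrichment trends.

Simulates one dataset at the field design size (7 plots × 9 years × 5
compartment strata) with compartment-specific temporal trends, fits the four
candidate fixed-effect structures by ML, and reports the AIC ranking; the
best model is refit with the restricted-likelihood adjustment and its
variance components printed.
"""

import warnings

from pulse15n.simulate import simulate_enrichment_glmm, trend_design
from pulse15n.studies import COMPARTMENT_TRENDS, REPORTED_GAMM_TRUTH
from pulse15n.trend import select_model

truth = REPORTED_GAMM_TRUTH
data = simulate_enrichment_glmm(
    trend_design(),
    intercept=truth["intercept"],
    contrasts=truth["contrasts"],
    smooth=COMPARTMENT_TRENDS,
    sd_plot=truth["sd_plot"],
    sd_resid=truth["sd_resid"],
    rho=truth["rho"],
    seed=4,
)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    summary, fits, best = select_model(data)

print("candidate-model ranking (ML fits):")
print(summary.round(3).to_string(index=False))
print("\nbest model refit with the restricted-likelihood adjustment:")
print(f"  SD(plot)  {best.sd_plot:.3f}  (truth {truth['sd_plot']})")
print(f"  SD(resid) {best.sd_resid:.3f}  (truth {truth['sd_resid']})")
print(f"  rho       {best.rho:.3f}  (truth {truth['rho']})")
print("\nthe interaction model should dominate (Akaike weight near 1): the "
      "simulated compartments genuinely follow different time trends.\n"
      "(intercept/contrast estimates are not printed against their simulation "
      "values here: under the interaction model each compartment's centered "
      "smooth absorbs part of its mean level, so the contrasts are not "
      "directly comparable across parameterizations.)")
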