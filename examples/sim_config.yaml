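# Example simulation config for `pulse15n simulate --config examples/sim_config.yaml`.
# Keys mirror pulse15n.simulate.SimulationConfig; omitted keys keep their
# defaults (7 plots, years 2007-2015, default transfer rates and noise).
n_plots: 7
seed: 42
moss_retention: 0.66
rate_jitter_sd: 0.25
delta_noise_sd: 1.0
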