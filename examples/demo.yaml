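# Full-pipeline demo: active vs 3 kDa-filtered extract, dual tracers,
# 25 repeat injections over 0-84 hr. Run with:
#   isodrift run --config examples/demo.yaml
outdir: isodrift_demo
seed: 1
stages: [simulate, quantify, drift, screen]
scenarios: [active, filtered]
n_planted_ms2: 14
n_decoy_ms2: 50
fragment_mz: 308.0912
trend_alpha: 0.05
balance_time_hr: 24.0
simulation:
  noise_cv: 0.05
  mass_error_ppm_sd: 1.0
  rt_jitter_sd_min: 0.02
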