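# Simulate, fit and analyze a synthetic two-arm study:
#   spmsens run --config examples/two_arm.yaml --stages simulate,fit,ppc,gcomp
outdir: spmsens_output
seed: 11
design:
  M: 8
terms:
  longitudinal: ["1", "trt", "t", "trt:t"]
  hazard: ["1", "trt", "t"]
mcmc:
  chains: 2
  burn_in: 1500
  draws: 1000
  thin: 3
simulate:
  kind: two_arm
  N: 300
sensitivity:
  prior_low: -2.0
  prior_mode: -1.0
  prior_high: 0.0
  sigma_mode: group
profiles:
  - label: control
    values: {trt: 0.0}
  - label: treated
    values: {trt: 1.0}
gcomp:
  n_draws: 24
  n_mc: 20000
  summary_visits: [4, 8]
  contrast_pairs: [["treated", "control"]]
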