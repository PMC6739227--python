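# Full-structure cohort emulation: 12 visits, 4-level baseline viral-load
# factor, treatment, symptom score, informative dropout, intermittent gaps.
#   spmsens run --config examples/hiv_cohort.yaml --stages simulate,fit,gcomp
outdir: spmsens_cohort
seed: 3
design:
  M: 12
terms:
  longitudinal: ["1", "vl_0_500", "vl_500_5k", "vl_5k_30k", "symptoms", "art",
                 "t", "vl_0_500:t", "vl_500_5k:t", "vl_5k_30k:t", "symptoms:t", "art:t"]
  hazard: ["1", "vl_0_500", "vl_500_5k", "vl_5k_30k", "symptoms", "art",
           "t", "t2", "art:t"]
mcmc:
  chains: 2
  burn_in: 2000
  draws: 1500
  thin: 3
simulate:
  kind: hers_like
  N: 400
  intermittent_rate: 0.076
sensitivity:
  prior_low: -2.0
  prior_mode: -1.0
  prior_high: 0.0
  sigma_mode: group
profiles:     # symptom score fixed at 0; reference viral-load group is >30k
  - label: vl_high_ref_no_art
    values: {vl_0_500: 0, vl_500_5k: 0, vl_5k_30k: 0, symptoms: 0, art: 0}
  - label: vl_low_no_art
    values: {vl_0_500: 1, vl_500_5k: 0, vl_5k_30k: 0, symptoms: 0, art: 0}
  - label: vl_high_ref_art
    values: {vl_0_500: 0, vl_500_5k: 0, vl_5k_30k: 0, symptoms: 0, art: 1}
  - label: vl_low_art
    values: {vl_0_500: 1, vl_500_5k: 0, vl_5k_30k: 0, symptoms: 0, art: 1}
gcomp:
  n_draws: 32
  n_mc: 10000
  summary_visits: [6, 12]
  contrast_pairs:
    - ["vl_low_no_art", "vl_high_ref_no_art"]
    - ["vl_low_art", "vl_high_ref_art"]
    - ["vl_high_ref_art", "vl_high_ref_no_art"]
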