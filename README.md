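# spmsens

Shared parameter models for longitudinal studies with informative
dropout, with a transparent, Δ-based sensitivity analysis for the
unverifiable conditional-independence assumption.

## The problem

In long-term follow-up studies (the motivating setting is repeated CD4
counts in an HIV cohort with 12 scheduled visits), subjects who drop out
early often differ systematically from completers even after
conditioning on what was observed — missingness that is not at random.
Shared parameter models (SPMs) handle this by linking a linear mixed
model for the complete outcome,

    Y_ij = x_ij' β + b_i1 + b_i2 t_j + ε_ij,      ε_ij ~ N(0, σ_ε²),

to a discrete-time probit hazard of dropout at visit l,

    λ_il = 1 − Φ( x_{S,il}' α + γ₁ b_i1 + γ₂ b_i2 ),

through shared random effects b_i ~ N(0, Σ_b) (random intercept and
slope; Σ_b parameterized by a modified Cholesky decomposition).  Given
b_i and covariates, outcome and dropout are assumed independent — an
assumption the observed data can never verify, so inference about
post-dropout behavior needs a sensitivity analysis.

The package's core results:

* **Default extrapolation in closed form.** Under this SPM, the
  conditional law of b_i given a subject's observed outcomes and dropout
  visit is a *closed skew-normal* distribution — a bivariate Gaussian
  density times one probit factor per hazard term, normalized by a
  Gaussian orthant probability.  Post-dropout outcomes inherit this law
  additively, so the model-implied ("default") imputation distribution
  is exact and samplable.
* **Δ-based sensitivity model.** Post-dropout trajectories may deviate
  from the default by a piecewise-linear slope change
  Δ_i = a · (M − S_i)/(M − 1) · σ_{b_i2}, where a is a single global
  sensitivity parameter with an informative prior (triangular on
  [−2, 0], mode −1 by default) and σ_{b_i2} is the posterior SD of the
  subject's random slope.  a = 0 reproduces the default exactly, and no
  value of a ever changes the fit to the observed data.
* **G-computation.** Marginal (population-averaged) covariate effects
  are obtained by Monte-Carlo integration over the fitted model at fixed
  covariate profiles, under both extrapolations, with full posterior
  uncertainty.

Estimation is Bayesian, by a blocked Gibbs sampler with latent-normal
(probit) augmentation; model assessment uses a χ² posterior predictive
check.

## Worked example

```python
import spmsens as sp

# a synthetic two-arm study: 300 subjects, 8 visits, informative dropout
cfg = sp.two_arm_config(N=300, M=8, seed=11)
df, truth = sp.make_dataset(cfg)

model = sp.SharedParameterModel.from_dataframe(
    df, cfg.design, cfg.long_spec, cfg.haz_spec)
res = model.fit(mcmc=sp.MCMCConfig(chains=2, burn_in=800, draws=1200, thin=2, seed=5))
print(res.summary().round(2).head(6))
```

```
             mean    sd  2.5%  97.5%
parameter
beta[1]     -0.57  0.06 -0.68  -0.46
beta[trt]    0.32  0.09  0.15   0.49
beta[t]     -1.31  0.13 -1.56  -1.07
beta[trt:t]  0.65  0.17  0.31   0.97
alpha[1]     1.25  0.10  1.06   1.46
alpha[trt]  -0.36  0.10 -0.57  -0.16
```

(`beta[1]` / `alpha[1]` are the intercept terms, named after the design
term "1".)  The generating values were β = (−0.5, 0.3, −1.2, 0.4) and
α = (1.1, −0.2, 0.8): every posterior mean sits within about two
posterior SDs of its truth.  The association draws (`gamma[1]`,
`gamma[2]`, truth 0.23 and 0.28) are clearly positive — subjects with
lower intercepts and steeper declines drop out sooner, so an ignorable
analysis would understate the decline.

Sensitivity analysis by G-computation:

```python
profiles = [sp.CovariateProfile("control", {"trt": 0.0}),
            sp.CovariateProfile("treated", {"trt": 1.0})]
g = res.gcompute(profiles, sp.SensitivityConfig(),
                 n_draws=24, n_mc=20_000, seed=7,
                 summary_visits=(8,), contrast_pairs=[("treated", "control")])
print(g.contrast_summary[["summary", "default_mean", "sensitivity_mean"]])
```

```
        summary  default_mean  sensitivity_mean
0       mean_v1        0.3198            0.3198
1       mean_v2        0.4075            0.3956
...
7       mean_v8        0.9396            0.8043
8  change_v1_v8        0.6198            0.4845
```

Under the default extrapolation the treated-vs-control difference in
mean change from baseline to visit 8 is ≈ 0.62; under the sensitivity
prior (post-dropout slopes steeper by up to two SDs) it shrinks to
≈ 0.48, because in this synthetic study the treated arm drops out more
and is adjusted downward more.  The two analyses agree at baseline
(identical `mean_v1`), as they must: the sensitivity machinery never
touches observed data.  `g.summary` also carries 95% credible intervals
and flags which exclude zero; `g.plot_effects()` draws the interval
plot.

A YAML-driven CLI covers the same pipeline:
`spmsens simulate|fit|extrapolate|gcomp|ppc|run --config config.yaml`.

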