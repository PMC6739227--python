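# Methods

## Model

For subject i with scheduled visits j = 1..M at standardized times
t_j = (j−1)/(M−1) ∈ [0, 1]:

* Longitudinal outcome: Y_ij = x_ij'β + z_ij'b_i + ε_ij with
  z_ij = (1, t_j), ε_ij ~ iid N(0, σ_ε²), b_i ~ N(0, Σ_b).  Σ_b is
  parameterized by the modified Cholesky decomposition
  b_i1 = e_i1, b_i2 = δ b_i1 + e_i2, Var(e_ik) = σ_k², which keeps Σ_b
  positive definite for any finite δ and positive σ_k.
* Dropout: S_i is the last attended visit (S_i = M is administrative
  censoring).  The discrete hazard at visit l = 1..M−1 is probit,
  λ_il = 1 − Φ(x_{S,il}'α + (W_il b_i)'γ_l).  The package supports
  visit-specific γ_l in the likelihood, extrapolation and G-computation
  layers; model *fitting* uses the shared-γ form (one γ ∈ R² for all
  visits), which is the parameterization of the motivating application
  and is well identified.  W defaults to the identity.
* Conditional independence: given b_i and covariates, Y_i ⊥ S_i.
  Intermittent (pre-dropout) missingness is treated as latently
  ignorable and handled by row deletion in the longitudinal likelihood;
  hazard terms still span every visit up to S_i.

The observed-data likelihood contribution is
f(Y_i^o | b_i) f(S_i | b_i) f(b_i), with the dropout factor having three
branches: an event at visit 1; survival×event for interior dropout; and
a pure survival product for completers.

## Priors and posterior computation

Priors follow weakly informative conventions for this model class:
β, δ ~ N(0, 100); α, γ ~ N(0, 4); σ_ε² ~ Inverse-Gamma(0.001, 0.001)
(shape/rate); σ_1, σ_2 ~ Uniform(0, 5).

Sampling is a blocked Gibbs sampler with two layers of data
augmentation: the subject random effects b_i, and one latent normal per
hazard term (the classical latent-variable representation of the probit
link).  Every full conditional is then conjugate — Gaussian for β,
(α, γ), b_i and δ; inverse-gamma for σ_ε²; inverse-gamma truncated to
(0, 25) for σ_k² (inverse-CDF draw, accounting for the uniform prior on
the SD scale).  Chains beyond the first start from overdispersed points.
Default run lengths (3 chains, 5000 burn-in, thinning by 5, 3000
retained per chain) mirror common practice for this model; tests and the
acceptance script use shorter, config-driven runs.

Known property: the association γ (and parameters entangled with it)
mixes slowly at small N because of the b↔γ coupling in the augmented
space — lag-1 autocorrelations near 0.9 at N = 300 and worse at N = 60.
Convergence should always be checked (the `fit` CLI exits nonzero when
the PSRF exceeds 1.1).  The PSRF reported is the classic between/within
ratio floored at 1; effective sample sizes come from arviz.

## Default extrapolation: the closed skew-normal law

The conditional density of b_i given (Y_i^o, S_i, covariates) is
proportional to φ(b; μ_i, Ω_i) ∏_l Φ(c_il + d_il'b): the Gaussian part
is the conjugate update of N(0, Σ_b) by the observed outcome rows; each
hazard term contributes one probit factor (survival terms with positive
sign; the event term at S_i < M with flipped sign because
λ = Φ(−η)).  A subject dropping out at S < M has m = S factors,
a completer m = M−1.  This is a closed skew-normal (CSN) distribution
whose normalizing constant is an m-dimensional Gaussian orthant
probability.

Numerics:

* Orthant probabilities: scipy's quasi-Monte-Carlo integrator with a
  fixed internal stream (all evaluations deterministic).  Default
  absolute tolerance 1e-8; both absolute and relative tolerances are
  exposed.  The normalizing constant is computed lazily — samplers and
  moment routines do not need it.
* Exact moments (`csn_moments`): the skew factors are rewritten as the
  orthant event of the augmented Gaussian V = c + Db − U, U ~ N(0, I_m);
  CSN moments then follow from truncated-MVN moments of V (Tallis-type
  first- and second-moment identities, requiring m-, (m−1)- and
  (m−2)-dimensional CDFs) by linear-Gaussian conditioning.  Validated
  against 2-D quadrature and rejection sampling in the test suite,
  since closed-form CSN moment tables are easy to get wrong.
* Fast marginal moments (`csn_marginal_moments_fd`): mean and variance
  of one coordinate from central finite differences (step 0.4) of the
  log orthant probability along an exponential tilt — three m-dim CDF
  calls instead of O(m²) lower-dimensional ones, relative accuracy
  ~1e-4.  Used where the value feeds a group average.
* Sampling (`sample_csn`): exact rejection — propose N(μ, Ω), accept
  with probability ∏Φ(·) ≤ 1; the acceptance rate equals the
  normalizing constant, and constant (zero-slope) factors are skipped.
  Below an acceptance floor (default 1e-4) the sampler raises and
  recommends `sample_csn_gibbs`, an augmented-orthant Gibbs chain
  (truncated-MVN Gibbs on V, then the exact Gaussian b | V) whose draws
  are MCMC rather than independent.

Missing outcomes are drawn as Y_ik = x_ik'β + z_ik'b + ε_ik with one
shared b per replicate and independent residuals — the "default"
extrapolation implied by the fitted SPM.

## Sensitivity analysis

Post-dropout outcomes follow the piecewise-linear deviation
Y_ik = x_ik'β + b_i1 + b_i2 t_k + Δ_i (t_k − t_{S_i})_+ + ε_ik with b
from the *default* CSN law and Δ_i = a (M − S_i)/(M − 1) σ_{b_i2}.
Thus: Δ_i = 0 for completers; a·σ for dropout right after baseline;
a/(M−1)·σ for dropout at the penultimate visit.  The global parameter a
has a triangular prior on [−2, 0] with mode −1 by default (at most a
two-SD extra decline, centered at one SD), is drawn once per posterior
draw of θ (outside the per-profile Monte-Carlo loop), and never enters
the observed-data fit — sensitivity settings cannot change posterior
draws, which the tests check bit-for-bit.

σ_{b_i2} is the slope SD of the subject's CSN law.  Two modes:
`exact` recomputes it per subject (per replicate in G-computation) from
the closed-form moments; `group` averages exact values within covariate
groups and assigns the group mean — the approximation used at cohort
scale, where each exact value costs high-dimensional CDFs (m up to 11
for a 12-visit study).  Inside G-computation the grouping key is the
covariate profile itself and the group mean is estimated from a
subsample of dropout replicates (default 32 per dropout-visit stratum)
using the fast tilt route; the subsample size and CDF tolerance are
exposed.  No tolerance for the adequacy of the group approximation is
prescribed; both modes are available and comparable.

Sensitivity draws share the random streams of the default draws, so
a = 0 anchors exactly (bit-level), and the mean shift at visit k equals
Δ_i (t_k − t_{S_i})_+ identically.

## G-computation

For each retained posterior draw θ and covariate profile: draw a;
simulate n_mc complete-outcome + dropout replicates from the SPM at the
profile; truncate each at its dropout visit; fill the missing visits
from both extrapolations; average summaries (per-visit completed means
and changes from baseline to configured visits, default visits 6 and 12
capped at M).  Replicates are processed in dropout-visit groups, within
which the Gaussian update, skew factors and design rows coincide, so
imputation is batched linear algebra — this is what makes n_mc = 100N
(the recommended scale, since Monte-Carlo error must be small relative
to sampling error) affordable.  Profile contrasts give marginal
covariate effects; posterior summaries are means and central 95%
intervals with an excludes-zero flag.  The number of posterior draws
processed (evenly spaced thinning) and n_mc are configuration.  Streams
are derived per (draw, profile) from the master seed, so serial and
parallel (joblib) execution agree exactly.

The headline correctness property — checked in the acceptance tests at
n_mc = 50,000 — is *marginal recovery*: under the default extrapolation
the G-computation means reproduce x_k'β at every visit for any γ,
because imputing from the exact conditional law reconstructs the joint.

## Posterior predictive check

The discrepancy is the χ² statistic conditional on (θ, b): summed
squared standardized residuals over observed entries.  For each posterior
draw, a full replicated study (same N, covariates and design; new b,
outcomes and dropout) is truncated to its replicated observed data and
the replicated discrepancy compared with the observed one; the reported
p-value is the exceedance probability.  The observed-side b comes from
the fit's augmentation, or is redrawn from each subject's CSN law
(`redraw_b=True`) when the check is applied to data the model was not
fitted to.  Conditioning the discrepancy on sampled b (rather than
marginalizing b out) is a choice; the marginalized variant would be a
straightforward extension.

## Synthetic data generator

`hers_like_config` emulates the structure of the motivating cohort:
M = 12 visits, a 4-level baseline viral-load factor (probabilities
0.25/0.30/0.20/0.25), binary antiretroviral treatment (prevalence 0.35),
an ordinal 0–5 symptom score (decaying probabilities), main effects and
time interactions in the outcome model, time and time² plus a
treatment×time term in the hazard, intermittent missingness at rate
0.076, and truth values set to posterior means reported for such a
cohort analysis — a realism convenience, not a reproduction claim.
`two_arm_config` is a compact variant (binary treatment only) used for
replicate studies.  Covariates are sampled independently; real cohort
covariates are correlated, and the generator makes no attempt to emulate
serial correlation beyond the shared random effects — passing tests
demonstrate internal validity of the machinery, not fit to any real
dataset.  Per-subject streams are spawned deterministically from the
master seed, so enlarging N leaves earlier subjects unchanged.

## Problem sizes in the tests and acceptance script

Replicate studies use N = 300, M = 8 with single short chains
(600 burn-in + 2500 draws) for calibration, and N = 150, M = 6 for the
posterior-predictive replicates; G-computation checks use n_mc up to
50,000.  These sizes give Monte-Carlo error well inside the asserted
bands while keeping the default test run quick.

## Known limitations

* Fitting assumes W = I, shared γ, and intercept+slope random effects
  (q = 2); the Δ rule itself presumes the (1, t) structure.
* The rejection sampler is exact but degrades in deep tails (handled by
  the Gibbs fallback); the PPC applied to grossly misspecified data uses
  that fallback.
* No serial correlation in the residuals (σ_ε² I), matching the model.
* The group-average σ_{b_i2} ignores within-group heterogeneity of the
  observed data; the exact mode quantifies the difference when needed.
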