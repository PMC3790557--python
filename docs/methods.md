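# Methods

## The model

`phenogamm` fits binomial generalized additive (mixed) models to long-format
presence/absence fruiting panels: monthly records `y_{i,k} ∈ {0,1}` of
whether plant *k* carried fruit in study month *i*. The full model on the
logit scale is

    logit P(y_{i,k} = 1) = β₀ + s₁(t_i) + s₂(c_i) + β_lag · y_{i−1,k} + b_k

where `s₁` is a smooth *interannual* trend over study month `t`, `s₂` a
*cyclic* smooth of calendar month `c` (period 12, function and first two
derivatives matching across the December–January boundary), `β_lag` a
lag-1 autocorrelation coefficient on the previous month's (completed)
status, and `b_k ~ N(0, σ²)` per-plant random intercepts. Removing terms
gives the reduced suite: M1 (both smooths), M2 (parametric linear trend +
seasonal), M3 (trend smooth only), M4 (seasonal only), M5 (intercept only).
For single-'species' simulation panels the lag and random-intercept terms
are omitted.

## Spline bases and penalties

Both smooths are cubic regression splines parameterised by their values at
knots (natural end conditions for `s₁`, periodic wrap for `s₂`), with
evenly spaced knots — over the observed month range for `s₁` and over one
period `[0, 12]` for `s₂`; regular monthly sampling makes even spacing the
natural choice. The penalty is the exact integrated squared second
derivative, computed in closed form from the banded value-to-curvature
matrices of the spline representation (verified in tests against numerical
quadrature, and against `scipy` natural/periodic interpolants at machine
precision).

Identifiability beside the intercept is enforced by a sum-to-zero
constraint over the fitting data, absorbed by a Householder
reparameterisation so every design column sums to zero exactly. Basis
dimension bookkeeping: a `max_dim = k` cubic term yields `k − 1` columns
after centring (penalty null space: the centred linear function); a cyclic
term yields `k − 2` (periodicity removes one dimension, centring removes
the constant, leaving an empty null space). Defaults `k = 10` (trend) and
`k = 8` (seasonal) follow common practice for decade-scale monthly series;
the results are insensitive to moderate changes.

Internally each smooth is re-expressed in the *natural parameterisation*
(eigenbasis of its centred penalty): null-space directions become ordinary
unpenalised coefficients and range-space directions carry an identity
penalty. All penalties are then diagonal, and random intercepts are just
one more identity-penalised block with `λ_re = 1/σ²` — one optimizer
handles smoothing parameters and the variance component jointly, mirroring
the mixed-model representation of penalized smooths and avoiding PQL
(known to behave poorly for Bernoulli data).

## Fitting

Coefficients minimise the penalized binomial deviance
`D(β) + Σ_j λ_j βᵀS_jβ` by iteratively reweighted least squares with step
halving; initialisation uses the standard working response from
`μ₀ = (y + ½)/2`, convergence is a relative penalized-deviance change
below 1e−8 (cap 200 iterations, flagged if hit). Unpenalised fits whose
fitted log-odds exceed ±15 are treated as (quasi-)separated: a warning is
raised and the fit is repeated with a small ridge, flagged on the result.

Smoothing parameters maximise a Laplace approximation to the marginal
likelihood in which unpenalised coefficients are profiled and penalized
coordinates integrated out:

    l_m = l(β̂) − ½ Σ λ_j‖b̂_j‖² + ½ Σ r_j log λ_j − ½ log det[(XᵀWX + S_λ)_pp]

(the determinant over penalized columns only). This is the same
approximation a Laplace GLMM fit of the mixed representation uses, and it
reduces exactly to the GLM log-likelihood when no penalized term is
present — which keeps likelihood-ratio comparisons across M1–M5 on one
scale. Optimisation is derivative-free (fixed-start coordinate pre-search
on a coarse log-λ grid, then Nelder–Mead over log λ, warm-starting the
inner IRLS), falling back to the best coarse-grid point if the simplex
fails; everything is deterministic given the data.

Unpenalised fits were validated against an independent Newton solver,
statsmodels GLM, and R's `mgcv` on identical knots (agreement ≤ 1e−6);
ML-selected fits agree with `mgcv`'s ML fits closely but not identically
(different marginal-likelihood internals), which the test suite asserts at
curve level.

## Inference

* **Posterior covariance.** `V_β = (XᵀWX + S_λ)⁻¹`, the Bayesian
  covariance implied by reading the penalty as a Gaussian prior; pointwise
  95% credible bands for a smooth are `f̂ ± 1.96·SE` on the logit scale.
* **Wald smooth tests.** The statistic is a rank-r pseudoinverse quadratic
  form built in *function space* — fitted term values over the observed
  covariate grid and the corresponding covariance — with
  `r = max(1, round(EDF))`. Function space makes the statistic invariant
  to basis parameterisation; the truncation keeps the effective estimation
  space. P-values come from the χ²_r upper tail. Both the fractional EDF
  and the integer rank actually used are reported.
* **EDF.** `tr[(XᵀWX + S_λ)⁻¹ XᵀWX]`, per term by summing the
  corresponding diagonal entries; monotone decreasing in λ (tested).
* **LRT.** `2(l_m^full − l_m^nested)` with a *structural* df rule: a cubic
  trend smooth counts 2 (its linear fixed part + one variance component),
  a cyclic smooth 1 (variance only; its constant is absorbed by the
  intercept), a parametric slope 1. Hence df = 3 for M1 vs M5 and df = 1
  for M1 vs M2. Variance components sit on the boundary under the null, so
  the plain χ² reference is conservative in that direction; this is
  documented, not corrected.

## Two-step structure selection

Step 1: LRT of M1 against M5; if M5 survives it is chosen. Otherwise M1 is
tested against M2–M4 and the most parsimonious structure not rejected wins
(parsimony by structural df; ties by larger LRT P-value; M1 if all are
rejected). Step 2: the winner's components are inspected against the zero
function — the trend smooth must have its 95% band exclude zero for at
least 10 study months, the seasonal smooth for at least 2 of 12 calendar
months (the permissive lower ends of the "about 10–12 / 2–3 months"
guidance; both configurable), and an M2 slope must have its 95% interval
exclude zero. Failing components are dropped and the label remapped to the
most parsimonious structure containing the survivors; a bare linear trend
maps to M2. Evaluation grids: the observed monthly grid for the trend, 12
mid-month points for the seasonal term. The decision is a deterministic
function of the fitted likelihoods and bands.

The selection machinery requires `alpha ∈ (0, 1)`; degenerate
`alpha ∈ {0, 1}` is rejected up front rather than given a convention.

## Missing-data imputation

Missed surveys (~6% of entries in the emulated design) are imputed per
plant by a two-state hidden Markov model with Bernoulli emissions, fitted
by Baum–Welch EM from a fixed deterministic start (initial (0.5, 0.5),
transition diagonal 0.7, emissions 0.25/0.75; stop at Δloglik < 1e−6 or
500 iterations). Missing months contribute unit emission likelihood. All
recursions are scaled; the forward–backward smoother was verified against
brute-force path enumeration (≤ 1e−10) and a log-domain implementation.
Each missing entry is replaced by the indicator of its smoothed posterior
fruit probability exceeding 0.5 (ties fall back to the previous month) so
the completed series stays binary for the lag term; the posterior
probability is also written to the imputation mask for users who prefer it.
All-0/all-1 observed series shortcut to a boundary-pinned emission model,
flagged. The lag column uses the completed (imputed) series throughout.

## Simulation study

Data are generated for 20 exchangeable plants over 120 months from the
structures M1/M3/M4/M5 with known functions; M1 is fitted with ML
smoothing selection; per replicate we record Wald P-values, the average
coverage (fraction of observed evaluation points where the band contains
the target) of each true function, and zero-function containment.
Exchangeability lets plant-months be aggregated to monthly binomial counts
before fitting — the likelihood is identical and fits ~20× faster; the
default 200 replicates per scenario run in well under a minute each.

**Reconstructed generating functions.** The original tables of true
function values are not available, so the package ships a reconstruction:

* trend `s₁`: logit shifts over study years 3 and 8 (+1.2) and year 5
  (−1.2), constant within the year with one-month linear shoulders;
* seasonal `s₂`: annual triangular pulse from a −0.5 logit baseline to a
  +1.0 peak (peak calendar month 6, half-width 3 months).

The amplitude and pulse width were fixed once by the scan in
`scripts/calibrate_generating_functions.py` so that matched-M1 power is ~1
and the coverage/containment summaries sit in their published ranges, and
are frozen in `phenogamm.simulate`. Two consequences are worth noting.
First, all function-dependent simulation summaries are approximate by
construction. Second, the seasonal false-acceptance rate when fitting M1
to trend-only (M3) data comes out near 0.02 here, far below the
historically reported 0.18: year-long trend episodes project onto every
calendar month equally, so there is no structural leakage into the cyclic
term, and the rank-rounded Wald test is mildly conservative for a term
whose smoothing parameter is selected to the boundary. An anticonservative
legacy variant of the smooth test (higher-rank statistic referred to a
fractional-df χ²) reproduces inflation of that rate several-fold, which is
the likely origin of the historical value; the package deliberately keeps
the well-calibrated test. The trend function does not integrate exactly to
zero over the study span (two good years against one bad year); fitted
smooths are sum-to-zero, so true functions are centred over the evaluation
grid before coverage is computed and the offset is absorbed by the
intercept.

## Synthetic community generator

`default_bwindi_profiles` emulates the structure of a long-term Afromontane
monitoring design: 33 species, 249 plants, 95 monthly surveys starting in
September, 25 focal species with ≥ 5 plants totalling 229, ~6% of entries
missing completely at random. Generating structures are spread over the
focal species as M1:7, M2:5, M3:9, M4:1, M5:3 across a range of sample
sizes. Species effect sizes are illustrative values typical of strongly
seasonal tropical fruiting records (seasonal ranges 1.8–3.0 logits,
episodic good/bad years of 1.2–1.8 logits placed in the later study years,
linear slopes 0.012–0.02 logit/month, random-intercept SDs 0.3–0.9,
persistence coefficients 0.8–1.5, baselines −1.4 to −0.4): they are not
estimates of any real forest. The generator draws each plant-month
sequentially because of the lag term; missingness is completely at random
(only the rate is emulated; the real design's per-plant clustering of
misses is not).

What the synthetic data do *not* emulate: observation error, mortality and
recruitment (all plants survive the whole window), covariate-driven
seasonality (no rainfall/temperature inputs), between-species correlation
in good years beyond what shared window placement induces, and
non-random missingness. Passing the recovery suite therefore demonstrates
that the estimation and selection machinery works under the model's own
assumptions at realistic sizes — not that those assumptions hold in any
particular field data set.

## Numerical choices and degenerate inputs

* Logit clipping at ±30 and IRLS weight floor 1e−10; a 1e−10 ridge on
  every linear solve.
* Smoothing parameters searched in log λ ∈ [−12, 18]; Nelder–Mead
  `xatol = 1e−3` — fitted curves are insensitive below this.
* Wald rank deficiency beyond tolerance reduces r with a warning.
* Negative LRT statistics beyond −1e−6 flag the comparison; small negative
  values are clamped to zero.
* Non-cyclic smooth evaluation outside the training range extrapolates
  linearly with a warning (the natural-spline continuation).
* Empty panels, non-binary statuses, duplicate plant-months and
  non-contiguous month indices are rejected with itemised messages.

## Known limitations

* Binomial/logit only; no Poisson or zero-inflated families.
* Lag-1 and random intercepts only; no random slopes, species-level random
  effects or richer AR structures.
* The Laplace ML criterion is an approximation; for very small panels its
  variance-component estimates can sit on the boundary (σ̂ = 0), which the
  selection machinery treats as an ordinary fit.
* The community-level fit at full size (hundreds of random-effect columns)
  is dense and slow (minutes); the pipeline therefore makes it optional.
* The first month of each plant's series is conditioned on (dropped from
  the likelihood) when the lag term is present — about 1% of rows at the
  default design.
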