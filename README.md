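# phenogamm

Binomial GAMMs for disentangling long-term trends, local anomalies and
seasonality in presence/absence fruiting phenology panels.

Long-term phenology monitoring typically produces monthly 0/1 records of
whether each marked plant carries fruit. Ecologists then want to separate
three very different signals in such panels: regular within-year
seasonality, multi-year trends or episodic "good/bad years", and
plant-level idiosyncrasy plus month-to-month persistence. `phenogamm`
implements that decomposition as a penalized-spline generalized additive
mixed model, for field ecologists and biostatisticians working with
presence/absence panels who want inferential answers (is the seasonality
significant? which months trended upward?) rather than descriptive
summaries.

## The model

For plant *k* in study month *t* with calendar month *c(t)*,

    logit P(y_{t,k} = 1) = β₀ + s₁(t) + s₂(c(t)) + β_lag·y_{t−1,k} + b_k,
    b_k ~ N(0, σ²)

with `s₁` a cubic regression spline (long-term trend), `s₂` a cyclic cubic
spline of period 12 (seasonality), and the lag and random-intercept terms
absorbing temporal and plant-level dependence. Coefficients minimise the
penalized deviance `D(β) + Σ λ_j βᵀS_jβ` (curvature penalties `S_j`);
smoothing parameters and σ are selected jointly by Laplace-approximate
maximum marginal likelihood. Reduced structures form a suite: M1 (both
smooths), M2 (linear trend + seasonal), M3 (trend only), M4 (seasonal
only), M5 (intercept only). On top of the fits the package provides Wald
χ² tests for smooth terms, Bayesian credible bands, likelihood-ratio
structure selection with zero-function inspection, hidden-Markov
imputation of missed surveys, per-species trend classification, a
simulation study of P-value reliability and band coverage, and a synthetic
multi-species panel generator, so the whole pipeline runs with no external
data.

## Worked example

```python
from phenogamm import generate_sim_panel, PhenologyGamm, two_step_select

panel = generate_sim_panel("M1", n_plants=20, n_months=120, seed=42)
res = PhenologyGamm.from_panel(panel, "M1", mixed=False).fit()
print(res.summary())
```

```
Binomial GAMM fit (logit link)
  structure: M1   mixed: False   n_obs: 2400   converged: True
  deviance: 3059.246   marginal logLik: -1557.765   total EDF: 14.07
  s(trend): edf=8.14 lambda=869.7 chi2=124.73 rank=8 p=3.493e-23
  s(seasonal): edf=4.93 lambda=4.375 chi2=125.11 rank=5 p=2.594e-25
```

The panel was simulated with both a bumpy multi-year trend and an annual
seasonal pulse, and the fit finds both: each smooth uses substantially
more effective degrees of freedom than a line (8.14 and 4.93), and both
Wald tests reject the zero function decisively. The two-step structure
selection agrees:

```python
dec, fits = two_step_select(panel, mixed=False)
```

```
chosen: M1 | step1: M1 | demoted: False
zero-exclusion fractions: s1 = 0.692  s2 = 0.917
  M1 vs M5: chi2=211.56 df=3 p=1.34e-45
  M1 vs M2: chi2=100.11 df=1 p=1.44e-23
  M1 vs M3: chi2=116.87 df=1 p=3.06e-27
  M1 vs M4: chi2=103.82 df=2 p=2.85e-23
```

Every reduced structure is rejected (note the structural df: dropping the
trend smooth costs 2, the cyclic smooth 1), and the retained smooths
exclude zero over 69% / 92% of their evaluation grids — far above the
10-month / 2-month retention thresholds, so nothing is demoted.
`res.credible_band("trend")` returns the band behind those fractions as a
table; `classify_trend` turns it into per-month positive/negative/none
labels.

A command-line interface mirrors the library
(`phenogamm simulate-panel | impute | fit | select | classify | experiment
| pipeline | report`); `phenogamm pipeline --outdir run/` generates the
default 33-species synthetic community, imputes, selects a structure per
focal species, writes trend labels, a model-count table and a JSON run
manifest.

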