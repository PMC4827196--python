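# Statistical methods

This document states the model the package fits, the estimators it exposes,
the degrees-of-freedom and resampling conventions, the scope of the
simulation generator, and the numerical choices that matter for
reproducibility.

## Model

One Cq observation per well (technical replicates are averaged first unless
modelled explicitly):

```
Cq[i,j,s,k] = mu[i,j] + A[j,s] + gamma[i] * x[k] + eps[i,j,s,k]
A[j,s] ~ N(0, sigma_S^2),   eps[i,j,s,k] ~ N(0, sigma_j^2)
```

- `i` — gene role, target or reference;
- `j` — sample group: case, control, or standard (the dilution series);
- `s` — biological sample; `A[j,s]` is shared by every well of that sample,
  inducing the within-sample correlation that pairs target and reference;
- `x[k]` — number of 2-fold dilutions (0 for case/control wells under
  standard-curve designs);
- `gamma[i]` — slope of Cq on `x`, the inverse log2 amplification
  efficiency: `AE[i] = 2^(1/gamma[i])`, so perfect doubling is
  `gamma = 1`. A per-group slope `gamma[i,j]` is available for designs
  that dilute the biological samples themselves instead of running a
  separate standard curve (`efficiency_structure="estimated_by_group"`).

Residual variances may be per sample group (`sigma_j^2`, the default) or
pooled. Fitting maximises the ML or REML criterion: the fixed effects are
profiled out by generalized least squares at each value of the variance
parameters, and the profiled criterion is maximised over log standard
deviations. `Var[theta_hat] = (X' V_hat^-1 X)^-1` over all fixed effects,
including the standard-curve intercepts (nuisance) and, when estimated, the
slopes.

Library default is REML with per-group residual variances — standard
small-sample practice. The simulation benchmark deliberately uses ML with
a pooled residual variance instead (see "Simulation scope" below).

## The ΔΔCq contrast and its variance

```
c(theta) = (mu[tgt,case]/g_tgt - mu[ref,case]/g_ref)
         - (mu[tgt,ctrl]/g_tgt - mu[ref,ctrl]/g_ref)
```

`2^(-c)` is the fold change. Four standard errors:

- **naive** — refit with `gamma ≡ 1` and the dilution data dropped; the
  classical ΔΔCq. With a pooled residual variance and a balanced design
  this reproduces the two-sample t-test on per-sample differences exactly
  (the test suite asserts it).
- **EC (plug-in)** — `se^2 = g_mu' Var[theta_hat] g_mu` where `g_mu` is the
  contrast gradient with the `gamma` entries zeroed: the slope estimates
  are treated as known constants.
- **ECVA1 (delta method)** — `se^2 = g' Var[theta_hat] g` with the full
  analytic gradient: `±1/gamma` for the mean cells and
  `-sign * mu/gamma^2` terms for the slopes. First-order error
  propagation through the nonlinear contrast.
- **ECVA2 (Monte Carlo)** — draw `theta ~ N(theta_hat, Var[theta_hat])`
  (default 10,000 draws), evaluate `c(theta)` on each draw, report the
  sample SD. Draws with any `|gamma|` inside the near-zero guard band
  (default 0.05) are rejected; a warning is raised if more than 1% are
  lost. This does not linearise the contrast and therefore picks up
  curvature that ECVA1 misses when the slopes are poorly determined.

All three efficiency-corrected methods share one fit, so their point
estimates are identical by construction; only the uncertainty differs.

Two-sided p-values and confidence intervals use a t reference distribution
with the **containment** degrees of freedom

```
eta = n_obs - n_fixed - n_random_levels
```

which is exact in the balanced designs this model targets (e.g. 46 - 8 - 17
= 21 for a paired 16+5-sample cohort with a 7-step curve; 36 - 8 - 13 = 15
for the benchmark simulation design). A manual override is available for
designs where another convention is wanted. Containment is deliberately
conservative for the naive sub-model (it counts the sample levels even
though the classical test would use `2n - 2`).

## Bootstrap

**Nonparametric (block + residual).** Case and control sample identifiers
are resampled with replacement within their group; each drawn sample
carries its matched target and reference wells together (preserving the
within-sample dependence), and a sample drawn twice contributes two
independent random-effect levels. The dilution series has one well per
step, so it is rebuilt by residual resampling: per gene, an OLS line of Cq
on dilution steps is fitted and its centred residuals are resampled onto
the fitted line. Each resample is refitted with the full mixed model.

**Parametric.** New random effects and residual noise are drawn from the
fitted variance components and added to the fitted means, then refitted.

Summaries: mean of the draws, sample-SD standard error, inverse-ECDF
percentile interval (order statistic at `ceil(q*n)`), and the add-one
sign-count p-value `p = min(1, 2(1 + min(#{d<=0}, #{d>=0}))/(B+1))`.

## Simulation scope

`simulate_dataset` draws from exactly the model above: homoscedastic noise
(`sigma`), one standard-curve sample per experiment observed at
`x = 1..K` for both genes, and no technical replicates. Defaults are the
benchmark study conditions: `n = 6` samples per group, `K = 6`,
`sigma_S = sigma = 1`, log2-efficiencies `alpha_tgt = 0.80`,
`alpha_ref = 0.95` (`gamma = 1/alpha`), effect `delta = 10/9` under the
alternative — implemented by shifting `mu[tgt,case]` by `delta * gamma_tgt`
so the true contrast is exactly `delta`. Baseline means are immaterial
(the model is location invariant).

The benchmark **analysis** model is ML with a pooled residual variance
(`SimulationConfig.analysis_spec`). Both choices matter for matching the
benchmark error rates: REML and/or per-group residual variances give
systematically more conservative rejection rates (EC FPR ≈ 0.064 instead
of ≈ 0.073, EC TPR ≈ 0.30 instead of ≈ 0.38), because the ML variance
estimates are biased low exactly the way the benchmarked procedures were
originally run. The library default for data analysis remains REML.

Rates are fractions of significant tests with exact Clopper–Pearson 95%
intervals. Every dataset receives its own seed spawned from the root seed,
so results are reproducible and independent of evaluation order, and
running one hypothesis reproduces the corresponding rows of a joint run.

`mean_se_curves` reports both the mean and the median standard error per
(K, n) design cell. The median is the summary to trust at small K: the
delta-method se contains a `1/gamma_hat^2` factor, and since `gamma_hat`
is Gaussian with positive density at zero this factor has no finite
population mean — the empirical mean is dominated by rare near-zero slopes
and does not stabilise at any replication count.

## Numerical choices

- The profiled criterion and its analytic gradient (envelope theorem; REML
  adds a `tr[(X'V^-1X)^-1 X'V^-1 (dV) V^-1 X]/2` term) are evaluated with
  direct LAPACK calls (Cholesky factorisations and triangular solves); a
  single fit of the benchmark design takes a few milliseconds, which is
  what makes ~160,000 bootstrap refits per acceptance run feasible.
- Optimisation is L-BFGS-B over log standard deviations, bounded in
  [-15, 8], from three deterministic starts anchored at the OLS residual
  scale of the data (deterministic rather than random so every fit is
  bit-reproducible). Gradient tolerance 1e-8.
- Bootstrap and simulation refits are warm-started at the original fit's
  variance optimum with a relaxed gradient tolerance (1e-5); the
  deterministic multi-starts remain as a fallback when a warm start fails.
- A variance component reaching the lower boundary (sigma_S^2 -> 0) raises
  a warning; estimates remain valid (the GLS step is unaffected).
- Near-zero estimated slopes (|gamma| < 0.05 by default) raise warnings
  everywhere and are rejected from ECVA2 Monte Carlo draws; `gamma = 0`
  raises an error since the contrast is undefined there.
- The fit was cross-checked during development against an independent
  mixed-model implementation (R's lme4) on the benchmark design: fixed
  effects, variance components and log-likelihood agree to 6 decimals.

## Limitations

- The model assumes Gaussian Cq noise and a linear dilution response over
  the observed range; amplification inhibition at high concentrations or
  stochastic dropout near the detection limit are not modelled.
- One standard-curve sample per gene is the supported standard-curve
  layout; several curves per gene would need to be pre-averaged or encoded
  as separate samples.
- Multiple target/reference pairs are analysed independently, one row
  each, with no multiplicity correction; apply your own (e.g.
  Benjamini–Hochberg on the p-value column) when screening many genes.
- The containment df rule is exact only for balanced designs; use
  `df_rule="manual"` for seriously unbalanced ones.
- The nonparametric bootstrap requires at least a handful of samples per
  group to be meaningful (it resamples sample blocks) and exactly one
  target and one reference well per sample after replicate averaging.
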