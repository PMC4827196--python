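# ddcq — efficiency-corrected ΔΔCq inference for qPCR

Relative quantification by qPCR compares a target transcript between case
and control samples, normalised by a reference gene: the classical ΔΔCq
("double delta Cq") method. The amplification efficiency (AE) of each assay
is estimated from a standard-curve dilution series and plugged into the
ΔΔCq formula — usually as if it were known exactly. It is not: the
standard-curve slope is itself an estimate with sampling error, and ignoring
that error makes the reported standard errors too small, the confidence
intervals too short, and the false positive rate of the ΔΔCq test higher
than the nominal level.

`ddcq` fits the underlying linear mixed model jointly to the case/control
wells and the dilution series, and propagates the efficiency uncertainty
into the ΔΔCq standard error. It provides:

- **naive** — the classical ΔΔCq t-test with efficiencies fixed at perfect
  doubling (dilution data ignored);
- **EC** — efficiency corrected, efficiency estimates treated as known
  (the plug-in everyone uses);
- **ECVA1** — efficiency corrected and variance adjusted by the delta
  method over the full fixed-effect covariance;
- **ECVA2** — as ECVA1, with the variance evaluated by Monte Carlo
  integration instead of linearisation;
- **bootstrap** — nonparametric (block + residual) and parametric
  resampling with percentile intervals and sign-count p-values;
- a **simulation harness** that quantifies the false/true positive rate of
  each procedure and helps size a design (how many dilution steps, how many
  samples).

## The model

Each observed quantification cycle is modelled as

```
Cq[i,j,s,k] = mu[i,j] + A[j,s] + gamma[i] * x[k] + eps[i,j,s,k]
```

with gene role `i` (target/reference), sample group `j`
(case/control/standard), sample `s`, and `x[k]` the number of 2-fold
dilutions. `A[j,s] ~ N(0, sigma_S^2)` is a per-sample random effect shared
by both genes of a sample; `eps ~ N(0, sigma_j^2)` is residual noise (one
variance per group, or pooled). `gamma[i]` is the standard-curve slope —
the inverse log2 amplification efficiency, `AE = 2^(1/gamma)`. The
quantity of interest is the efficiency-weighted double difference

```
ddCq = (mu[tgt,case]/gamma[tgt] - mu[ref,case]/gamma[ref])
     - (mu[tgt,ctrl]/gamma[tgt] - mu[ref,ctrl]/gamma[ref])
```

and `2^(-ddCq)` is the fold change of the target transcript. Because the
estimated means are divided by estimated slopes, the slope uncertainty
belongs in the standard error — that is what ECVA1/ECVA2 and the bootstrap
add. See [docs/methods.md](docs/methods.md) for the full derivations and
numerical choices.

## Worked example

`examples/01_analyze_pair.py` reads a small inline Cq table (6 case and 6
control samples, a 6-step standard curve per gene) and runs all four tests:

```python
from ddcq import ModelSpec, analyze, fit_lmm, read_cq_table, results_frame

ds = read_cq_table("my_experiment.csv")   # or a text stream
fit = fit_lmm(ds, ModelSpec())
results = analyze(ds, methods=("naive", "EC", "ECVA1", "ECVA2"), seed=1)
print(results_frame(results).to_string(index=False))
```

Running the example prints:

```
estimated inverse log2-efficiencies (standard-curve slopes):
  gamma[reference] = 1.038  (AE = 1.950)
  gamma[target] = 1.244  (AE = 1.746)
sample variance sigma_S^2 = 0.968, residual df = 15

     label method  Estimate       se   t-value   df  p-value      LCL      UCL  fold_change
TAR vs REF  naive  1.350000 0.130907 10.312647  8.0 0.000007 1.048127 1.651873     0.392292
TAR vs REF     EC  1.027296 0.147266  6.975766 15.0 0.000004 0.713405 1.341187     0.490629
TAR vs REF  ECVA1  1.027296 0.149226  6.884160 15.0 0.000005 0.709228 1.345364     0.490629
TAR vs REF  ECVA2  1.027296 0.150388  6.830962 15.0 0.000006 0.706751 1.347841     0.490629
```

Two things to notice: the naive estimate (1.35) is biased because the true
efficiencies are below perfect doubling, and the EC-family point estimates
coincide while their standard errors widen as more of the efficiency
uncertainty is acknowledged. In designs with shorter dilution series the
ECVA1/EC gap is much larger (see `examples/04_design_curves.py`).

The other examples cover bootstrap intervals (`02_bootstrap_interval.py`),
error-rate simulation (`03_error_rates.py`) and design sizing
(`04_design_curves.py`); each runs in seconds.

## Command line

A thin CLI wraps the same functions:

```
ddcq validate my_experiment.csv
ddcq fit my_experiment.csv
ddcq test my_experiment.csv --method ec --method ecva1 --method boot --seed 1
ddcq simulate --mode rates --n-datasets 2000 --seed 1 --out rates.tsv
ddcq simulate --mode se-curves --config sim.yaml --out curves.tsv
```

Input is a delimited table with columns `gene_id, gene_role, sample_group,
sample_id, dilution_steps, cq` (and optionally `replicate_id`); different
column names can be mapped via the library's `dialect` argument. Outputs
are tidy TSV tables.

## Repository layout

- `src/ddcq/data.py` — Cq records, datasets, I/O, validation
- `src/ddcq/lmm.py` — the mixed-model engine (profiled ML/REML)
- `src/ddcq/inference.py` — contrast, delta-method/MC variance, t-tests
- `src/ddcq/bootstrap.py` — nonparametric and parametric bootstrap
- `src/ddcq/simulate.py` — data generator, error rates, design curves
- `src/ddcq/cli.py` — command-line front end
- `docs/methods.md` — statistical methods and numerical notes
- `examples/` — narrative example scripts
- `scripts/acceptance.py` — recompute the benchmark error rates
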