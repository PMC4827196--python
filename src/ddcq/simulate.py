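"""Synthetic qPCR data and error-rate estimation.

The generator draws datasets from the same mixed model the fitting code
assumes: case/control Cq values are ``mu[i,j] + A[j,s] + eps`` at zero
dilution, and a single standard-curve sample per experiment contributes, for
each gene, one well per dilution step ``x = 1..K`` at
``mu[i,std] + A[std] + gamma[i] * x + eps``.  Noise is homoscedastic
(``sigma``) on the Cq scale and the per-sample random effect has standard
deviation ``sigma_S``; the analysis model may still estimate group-specific
residual variances.

Default parameters are the benchmark conditions used throughout this
package: 6 samples per group, 6 dilution steps, sigma_S = sigma = 1, log2
amplification efficiencies 0.80 (target) and 0.95 (reference), and an
effect size of delta = 10/9 on the ddCq scale under the alternative.  The
alternative is generated by shifting the target case mean by
``delta * gamma_tgt`` so that the true contrast c(theta) equals delta
exactly.  Baseline means are immaterial to error rates (the model is
location invariant) and default to 25 cycles, a typical mid-range Cq.

False/true positive rates are estimated as the fraction of simulated
datasets whose test rejects at the chosen level, with exact Clopper-Pearson
binomial intervals.  All randomness flows through per-dataset seeds spawned
from one root seed, so results are reproducible and independent of
execution order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .bootstrap import bootstrap_distribution, bootstrap_p_value
from .data import CqRecord, QpcrDataset
from .inference import ddcq_test, delta_method_se, plugin_se
from .lmm import ConvergenceError, ModelSpec, fit_lmm

__all__ = [
    "SimulationConfig",
    "RateEstimate",
    "simulate_dataset",
    "estimate_rates",
    "mean_se_curves",
    "rate_confint",
]

HYPOTHESES = ("null", "alternative")
_SIM_METHODS = ("naive", "EC", "ECVA1", "ECVA2", "bootstrap_np")


def _default_spec() -> ModelSpec:
    # Benchmark analysis model: single residual variance, maximum likelihood.
    # The generator is homoscedastic, so the pooled fit is well specified; ML
    # (rather than REML) fixed-effect covariances are what the t-statistics
    # of the benchmarked procedures are built from.
    return ModelSpec(criterion="ML", residual_variance="pooled")


@dataclass(frozen=True)
class SimulationConfig:
    """Generator and study parameters for one simulation experiment."""

    n_per_group: int = 6          # samples in each of case and control
    K: int = 6                    # dilution steps per standard curve (x = 1..K)
    alpha_tgt: float = 0.80       # log2-AE of the target gene (gamma = 1/alpha)
    alpha_ref: float = 0.95       # log2-AE of the reference gene
    delta: float = 10.0 / 9.0     # true ddCq under the alternative
    sigma_S: float = 1.0          # sample random-effect SD
    sigma: float = 1.0            # residual SD (homoscedastic generation)
    mu_base: float = 25.0         # baseline mean Cq of every cell
    n_datasets: int = 2000
    level: float = 0.05
    seed: int | None = None
    methods: tuple = ("EC", "ECVA1")
    boot_B: int = 200             # bootstrap resamples per dataset, when used
    mc_draws: int = 10_000        # Monte Carlo draws for ECVA2, when used
    analysis_spec: ModelSpec = field(default_factory=_default_spec)

    def __post_init__(self):
        if self.K < 2 or self.n_per_group < 2:
            raise ValueError("need K >= 2 and n_per_group >= 2")
        if self.sigma < 0 or self.sigma_S < 0:
            raise ValueError("sigma and sigma_S must be nonnegative")
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        for m in self.methods:
            if m not in _SIM_METHODS:
                raise ValueError(f"unknown simulation method {m!r}")

    @property
    def gamma_tgt(self) -> float:
        return 1.0 / self.alpha_tgt

    @property
    def gamma_ref(self) -> float:
        return 1.0 / self.alpha_ref

    def true_means(self, hypothesis: str) -> dict:
        """Cell means placing the true contrast at 0 (null) or delta."""
        if hypothesis not in HYPOTHESES:
            raise ValueError(f"hypothesis must be one of {HYPOTHESES}")
        shift = self.delta * self.gamma_tgt if hypothesis == "alternative" else 0.0
        mu = {(role, group): self.mu_base
              for role in ("target", "reference")
              for group in ("case", "control", "standard")}
        mu[("target", "case")] += shift
        return mu


@dataclass(frozen=True)
class RateEstimate:
    """Fraction of significant tests with an exact binomial 95% interval."""

    method: str
    hypothesis: str
    rate: float
    numerator: int
    denominator: int
    ci_lower: float
    ci_upper: float


def simulate_dataset(config: SimulationConfig, hypothesis: str = "null",
                     rng=None) -> QpcrDataset:
    """Draw one dataset from the generating model.

    Case/control samples are observed undiluted for both genes; one
    standard-curve sample (its own random-effect level) is observed for both
    genes at dilution steps 1..K.  No technical replicates are generated.
    """
    rng = np.random.default_rng(rng)
    mu = config.true_means(hypothesis)
    gam = {"target": config.gamma_tgt, "reference": config.gamma_ref}
    recs = []
    for group in ("case", "control"):
        for s in range(config.n_per_group):
            A = rng.normal(0.0, config.sigma_S)
            for role in ("target", "reference"):
                cq = mu[(role, group)] + A + rng.normal(0.0, config.sigma)
                recs.append(CqRecord(
                    gene_id=role.upper()[:3], gene_role=role, sample_group=group,
                    sample_id=f"{group}_{s}", dilution_steps=0.0, cq=cq))
    A_std = rng.normal(0.0, config.sigma_S)
    for role in ("target", "reference"):
        for k in range(1, config.K + 1):
            cq = (mu[(role, "standard")] + A_std + gam[role] * k
                  + rng.normal(0.0, config.sigma))
            recs.append(CqRecord(
                gene_id=role.upper()[:3], gene_role=role, sample_group="standard",
                sample_id="std", dilution_steps=float(k), cq=cq))
    return QpcrDataset(tuple(recs), name=f"sim:{hypothesis}",
                       pairing={"TAR": "REF"})


def _dataset_pvalues(ds: QpcrDataset, config: SimulationConfig, rng) -> dict:
    """p-values of every requested method on one dataset (shared fit for the
    efficiency-corrected family)."""
    out = {}
    methods = [m.lower() for m in config.methods]
    spec = config.analysis_spec
    fit = None
    if any(m in ("ec", "ecva1", "ecva2") for m in methods):
        fit = fit_lmm(ds, spec, validate=False)
    for m in methods:
        if m == "naive":
            nfit = fit_lmm(ds, replace(spec, efficiency_structure="fixed_unity"),
                           validate=False)
            out["naive"] = ddcq_test(nfit, "naive", config.level).p_value
        elif m == "ec":
            out["EC"] = ddcq_test(fit, "ec", config.level).p_value
        elif m == "ecva1":
            out["ECVA1"] = ddcq_test(fit, "ecva1", config.level).p_value
        elif m == "ecva2":
            seed = int(rng.integers(2**31))
            out["ECVA2"] = ddcq_test(fit, "ecva2", config.level,
                                     n_draws=config.mc_draws, seed=seed).p_value
        elif m == "bootstrap_np":
            dist = bootstrap_distribution(ds, spec, B=config.boot_B, rng=rng)
            out["bootstrap_np"] = bootstrap_p_value(dist.draws)
    return out


def estimate_rates(config: SimulationConfig,
                   hypotheses: Sequence[str] = HYPOTHESES,
                   progress: bool = False) -> list[RateEstimate]:
    """Estimate FPR (null) and TPR (alternative) for each configured method.

    Each dataset receives its own seed spawned from ``config.seed``, so the
    result is reproducible and independent of evaluation order; fit failures
    are excluded from the denominator (with a warning above 2%).
    """
    root = np.random.SeedSequence(config.seed)
    hyp_seqs = root.spawn(len(HYPOTHESES))
    results: list[RateEstimate] = []
    for hyp in hypotheses:
        seq = hyp_seqs[HYPOTHESES.index(hyp)]
        children = seq.spawn(config.n_datasets)
        counts: dict[str, int] = {}
        totals: dict[str, int] = {}
        n_failed = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for d, child in enumerate(children):
                rng = np.random.default_rng(child)
                ds = simulate_dataset(config, hyp, rng)
                try:
                    pvals = _dataset_pvalues(ds, config, rng)
                except (ConvergenceError, np.linalg.LinAlgError, ValueError):
                    n_failed += 1
                    continue
                for m, p in pvals.items():
                    totals[m] = totals.get(m, 0) + 1
                    if p < config.level:
                        counts[m] = counts.get(m, 0) + 1
                if progress and (d + 1) % 1000 == 0:
                    print(f"[{hyp}] {d + 1}/{config.n_datasets} datasets done")
        if n_failed > 0.02 * config.n_datasets:
            warnings.warn(f"{n_failed}/{config.n_datasets} {hyp} datasets failed "
                          "to fit and were excluded", RuntimeWarning)
        for m in totals:
            k, n = counts.get(m, 0), totals[m]
            lo, hi = rate_confint(k, n)
            results.append(RateEstimate(
                method=m, hypothesis=hyp, rate=k / n, numerator=k,
                denominator=n, ci_lower=lo, ci_upper=hi))
    return results


def mean_se_curves(config: SimulationConfig,
                   K_values: Iterable[int], n_values: Iterable[int],
                   methods: Sequence[str] = ("EC", "ECVA1"),
                   hypotheses: Sequence[str] = HYPOTHESES):
    """Mean ddCq standard error per (K, n) design cell.

    For each grid cell and hypothesis, ``config.n_datasets`` datasets are
    simulated and the plug-in (EC) and delta-method (ECVA1) standard errors
    summarised; useful for choosing how many dilution steps and samples a
    design needs.  Returns a tidy DataFrame with both ``mean_se`` and
    ``median_se``: the delta-method se contains a 1/gamma_hat^2 term whose
    sampling distribution has no finite mean (gamma_hat is Gaussian with
    positive density at zero), so for small dilution series the mean is
    dominated by rare near-zero slopes and the median is the stable summary.
    """
    import pandas as pd

    for m in methods:
        if m not in ("EC", "ECVA1"):
            raise ValueError("mean_se_curves supports methods 'EC' and 'ECVA1'")
    root = np.random.SeedSequence(config.seed)
    rows = []
    cells = [(K, n) for K in K_values for n in n_values]
    cell_seqs = root.spawn(len(cells) * len(HYPOTHESES))
    i = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for K, n in cells:
            cfg = replace(config, K=K, n_per_group=n)
            for hyp in HYPOTHESES:
                seq = cell_seqs[i]; i += 1
                if hyp not in hypotheses:
                    continue
                ses = {m: [] for m in methods}
                for child in seq.spawn(config.n_datasets):
                    rng = np.random.default_rng(child)
                    ds = simulate_dataset(cfg, hyp, rng)
                    try:
                        fit = fit_lmm(ds, cfg.analysis_spec, validate=False)
                    except (ConvergenceError, np.linalg.LinAlgError):
                        continue
                    if "EC" in ses:
                        ses["EC"].append(plugin_se(fit))
                    if "ECVA1" in ses:
                        ses["ECVA1"].append(delta_method_se(fit))
                for m in methods:
                    rows.append({"K": K, "n": n, "hypothesis": hyp, "method": m,
                                 "mean_se": float(np.mean(ses[m])),
                                 "median_se": float(np.median(ses[m])),
                                 "n_datasets": len(ses[m])})
    return pd.DataFrame(rows)


def rate_confint(numerator: int, denominator: int,
                 level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided binomial confidence interval."""
    if not (0 <= numerator <= denominator) or denominator <= 0:
        raise ValueError("need 0 <= numerator <= denominator, denominator > 0")
    a = (1.0 - level) / 2.0
    k, n = numerator, denominator
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - a, k + 1, n - k))
    return lo, hi
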