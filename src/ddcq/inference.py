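"""Tests and confidence intervals for the efficiency-corrected delta-delta Cq.

The quantity of interest is the contrast

    c(theta) = (mu[tgt,case]/g_tgt - mu[ref,case]/g_ref)
             - (mu[tgt,ctrl]/g_tgt - mu[ref,ctrl]/g_ref)

with g the inverse log2 amplification efficiencies; 2**(-c) is the fold
change of the target transcript between cases and controls.  Because c
divides the estimated means by estimated slopes, the uncertainty of the
slope estimates propagates into the standard error.  Four estimators are
provided:

* ``naive``  -- gamma fixed at 1 (classical ddCq); dilution data ignored.
* ``ec``     -- efficiency corrected, but the slope estimates treated as
  known: the gamma rows/columns of Var[theta_hat] are suppressed (plug-in).
* ``ecva1``  -- efficiency corrected and variance adjusted by the delta
  method: se = sqrt(grad' Var[theta_hat] grad) over all fixed effects.
* ``ecva2``  -- as ecva1 but the variance is evaluated by Monte Carlo
  integration over N(theta_hat, Var[theta_hat]).

All point estimates for ec/ecva1/ecva2 coincide; only the standard error
(hence t, p, CI) differs.  Two-sided p-values and intervals use a t
reference distribution with the fit's residual degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .lmm import FittedModel, FixedEffects, ModelSpec, fit_lmm
from .data import QpcrDataset

__all__ = [
    "DdcqResult",
    "ddcq_contrast",
    "ddcq_gradient",
    "delta_method_se",
    "plugin_se",
    "mc_se",
    "ddcq_test",
    "fold_change",
    "analyze",
]

METHOD_LABELS = ("naive", "EC", "ECVA1", "ECVA2", "bootstrap_np", "bootstrap_param")


@dataclass(frozen=True)
class DdcqResult:
    """One row of a results table: the ddCq estimate and its inference."""

    method: str
    estimate: float          # ddCq, log2 units
    se: float
    t_value: float           # nan for bootstrap summaries
    df: float                # nan for bootstrap summaries
    p_value: float
    ci_lower: float
    ci_upper: float
    fold_change: float       # 2**(-estimate)
    level: float = 0.05
    mc_draws: int | None = None
    B: int | None = None
    seed: int | None = None
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "method": self.method, "Estimate": self.estimate, "se": self.se,
            "t-value": self.t_value, "df": self.df, "p-value": self.p_value,
            "LCL": self.ci_lower, "UCL": self.ci_upper,
            "fold_change": self.fold_change,
        }


def _gamma_for(theta: FixedEffects, role: str, group: str) -> float:
    """Slope dividing mu[role, group]: shared per role, or group-specific."""
    if role in theta.gamma:
        return theta.gamma[role]
    if (role, group) in theta.gamma:
        return theta.gamma[(role, group)]
    raise KeyError(f"no gamma available for {(role, group)}")


_SIGNS = {("target", "case"): 1.0, ("reference", "case"): -1.0,
          ("target", "control"): -1.0, ("reference", "control"): 1.0}


def _check_gammas(theta: FixedEffects, guard: float = 0.05) -> None:
    for key, g in theta.gamma.items():
        if g == 0:
            raise ZeroDivisionError(f"gamma for {key} is exactly 0")
        if abs(g) < guard:
            warnings.warn(f"gamma for {key} is {g:.4g}, near zero: the "
                          "efficiency-corrected contrast is unstable",
                          RuntimeWarning, stacklevel=3)


def ddcq_contrast(theta: FixedEffects, guard: float = 0.05) -> float:
    """Efficiency-weighted double difference c(theta) (the ddCq estimate)."""
    _check_gammas(theta, guard)
    return sum(sign * theta.mu[cell] / _gamma_for(theta, *cell)
               for cell, sign in _SIGNS.items())


def ddcq_gradient(theta: FixedEffects, labels, guard: float = 0.05) -> np.ndarray:
    """Analytic gradient of the contrast, aligned to the fixed-effect labels.

    Nuisance parameters (standard-curve intercepts) get zeros; gamma entries
    appear only when the labels carry them (i.e. efficiencies estimated).
    """
    _check_gammas(theta, guard)
    grad = np.zeros(len(labels))
    for i, lab in enumerate(labels):
        if lab[0] == "mu":
            cell = lab[1:]
            if cell in _SIGNS:
                grad[i] = _SIGNS[cell] / _gamma_for(theta, *cell)
        else:  # ("gamma", role) or ("gamma", role, group)
            if len(lab) == 2:
                role = lab[1]
                g = theta.gamma[role]
                num = sum(_SIGNS[(role, grp)] * theta.mu[(role, grp)]
                          for grp in ("case", "control") if (role, grp) in theta.mu)
                grad[i] = -num / g**2
            else:
                cell = lab[1:]
                if cell in _SIGNS:
                    g = theta.gamma[cell]
                    grad[i] = -_SIGNS[cell] * theta.mu[cell] / g**2
    return grad


def delta_method_se(fit: FittedModel) -> float:
    """First-order (delta-method) standard error of the contrast,
    propagating the full covariance of the fixed effects."""
    grad = ddcq_gradient(fit.theta, fit.labels, fit.spec.gamma_guard)
    var = float(grad @ fit.theta_cov @ grad)
    if var < -1e-10:
        raise np.linalg.LinAlgError(
            "covariance not positive semi-definite on the contrast gradient")
    return math.sqrt(max(var, 0.0))


def plugin_se(fit: FittedModel) -> float:
    """Plug-in standard error: the slope estimates are treated as known, so
    the gamma rows/columns of the covariance are suppressed.  Coincides with
    the delta-method se under fixed efficiency structures."""
    grad = ddcq_gradient(fit.theta, fit.labels, fit.spec.gamma_guard)
    keep = np.array([lab[0] == "mu" for lab in fit.labels])
    g = np.where(keep, grad, 0.0)
    var = float(g @ fit.theta_cov @ g)
    return math.sqrt(max(var, 0.0))


def mc_se(fit: FittedModel, n_draws: int = 10_000, seed: int | None = None,
          guard: float | None = None) -> float:
    """Monte Carlo standard error: draw theta ~ N(theta_hat, Var[theta_hat]),
    evaluate the contrast on each draw, return the sample SD.

    Draws whose gamma falls inside the near-zero guard band are rejected (and
    a warning raised if more than 1% are lost).  Reproducible given seed.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100")
    guard = fit.spec.gamma_guard if guard is None else guard
    rng = np.random.default_rng(seed)
    mean = np.empty(len(fit.labels))
    for i, lab in enumerate(fit.labels):
        if lab[0] == "mu":
            mean[i] = fit.theta.mu[lab[1:]]
        else:
            key = lab[1] if len(lab) == 2 else lab[1:]
            mean[i] = fit.theta.gamma[key]
    cov = fit.theta_cov
    if not np.any(cov):
        return 0.0
    draws = rng.multivariate_normal(mean, cov, size=n_draws, method="svd")

    gamma_idx = [i for i, lab in enumerate(fit.labels) if lab[0] == "gamma"]
    if gamma_idx:
        ok = np.all(np.abs(draws[:, gamma_idx]) >= guard, axis=1)
        n_rej = int(n_draws - ok.sum())
        if n_rej > 0.01 * n_draws:
            warnings.warn(f"{n_rej}/{n_draws} Monte Carlo draws rejected by the "
                          "near-zero gamma guard", RuntimeWarning, stacklevel=2)
        draws = draws[ok]

    # vectorized contrast over draws
    vals = np.zeros(len(draws))
    for cell, sign in _SIGNS.items():
        mu_i = fit.labels.index(("mu",) + cell)
        glab = ("gamma", cell[0])
        if glab not in fit.labels:
            glab = ("gamma",) + cell
        if glab in fit.labels:
            g = draws[:, fit.labels.index(glab)]
        else:
            g = _gamma_for(fit.theta, *cell)  # fixed gamma: constant
        vals += sign * draws[:, mu_i] / g
    return float(np.std(vals, ddof=1))


def fold_change(ddcq: float) -> float:
    """Fold change 2**(-ddCq) of the target transcript (case vs control)."""
    return float(2.0 ** (-ddcq))


def ddcq_test(fit: FittedModel, method: str = "ecva1", level: float = 0.05,
              n_draws: int = 10_000, seed: int | None = None,
              label: str = "") -> DdcqResult:
    """t-test and confidence interval for the ddCq contrast.

    ``method`` selects the standard error: ``naive``/``ec`` use the plug-in
    se (slope uncertainty suppressed -- for ``naive`` the fit itself must use
    the unit-efficiency structure), ``ecva1`` the delta-method se, ``ecva2``
    the Monte Carlo se (which requires a seed for reproducibility).
    """
    method = method.lower()
    est = ddcq_contrast(fit.theta, fit.spec.gamma_guard)
    if method in ("naive", "ec"):
        se = plugin_se(fit)
        draws = None
    elif method == "ecva1":
        se = delta_method_se(fit)
        draws = None
    elif method == "ecva2":
        se = mc_se(fit, n_draws=n_draws, seed=seed)
        draws = n_draws
    else:
        raise ValueError(f"unknown method {method!r} (bootstrap methods live in "
                         "ddcq.bootstrap)")
    df = fit.df_residual
    if se == 0.0:
        if est != 0.0:
            warnings.warn("zero standard error with a nonzero estimate; "
                          "p-value reported as 0", RuntimeWarning, stacklevel=2)
            t, p = math.inf, 0.0
        else:
            t, p = 0.0, 1.0
        half = 0.0
    else:
        t = est / se
        p = 2.0 * float(stats.t.sf(abs(t), df))
        half = float(stats.t.ppf(1.0 - level / 2.0, df)) * se
    name = {"naive": "naive", "ec": "EC", "ecva1": "ECVA1", "ecva2": "ECVA2"}[method]
    return DdcqResult(
        method=name, estimate=est, se=se, t_value=t, df=df, p_value=p,
        ci_lower=est - half, ci_upper=est + half, fold_change=fold_change(est),
        level=level, mc_draws=draws, seed=seed, label=label,
    )


def analyze(ds: QpcrDataset, spec: ModelSpec | None = None,
            methods=("EC", "ECVA1", "ECVA2"), level: float = 0.05,
            n_draws: int = 10_000, seed: int | None = None,
            B: int = 2000) -> list[DdcqResult]:
    """Analyze every target/reference pair of a dataset with the requested
    methods and return one :class:`DdcqResult` per pair and method.

    ``naive`` triggers a separate unit-efficiency fit (dilution data
    ignored); the efficiency-corrected methods share one fit per pair, so
    their point estimates are identical by construction.  Bootstrap methods
    (``bootstrap_np``, ``bootstrap_param``) delegate to :mod:`ddcq.bootstrap`.
    """
    spec = spec or ModelSpec()
    results: list[DdcqResult] = []
    for target, reference in ds.pairs():
        sub = ds.subset_pair(target, reference)
        label = f"{target} vs {reference}"
        wanted = [m.lower() for m in methods]
        fit = None
        if any(m in ("ec", "ecva1", "ecva2", "bootstrap_param") for m in wanted):
            fit = fit_lmm(sub, spec)
        for m in wanted:
            if m == "naive":
                from dataclasses import replace as _replace
                nfit = fit_lmm(sub, _replace(spec, efficiency_structure="fixed_unity"))
                results.append(ddcq_test(nfit, "naive", level, label=label))
            elif m in ("ec", "ecva1", "ecva2"):
                results.append(ddcq_test(fit, m, level, n_draws=n_draws,
                                         seed=seed, label=label))
            elif m in ("bootstrap_np", "bootstrap_param"):
                from . import bootstrap as _bs
                if m == "bootstrap_np":
                    dist = _bs.bootstrap_distribution(sub, spec, B=B, seed=seed)
                else:
                    dist = _bs.parametric_bootstrap(fit, B=B, seed=seed)
                res = _bs.bootstrap_summary(dist, level)
                results.append(
                    DdcqResult(**{**res.__dict__, "label": label}))
            else:
                raise ValueError(f"unknown method {m!r}")
    return results


def results_frame(results) -> "object":
    """Tabulate results in the Estimate/se/t-value/df/p-value/LCL/UCL layout."""
    import pandas as pd
    rows = []
    for r in results:
        d = r.to_dict()
        d = {"label": r.label, **d}
        rows.append(d)
    return pd.DataFrame(rows)
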