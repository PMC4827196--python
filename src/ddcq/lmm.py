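"""Linear mixed model engine for qPCR Cq tables.

The model for an observed quantification cycle is

    Cq[i,j,s,k] = mu[i,j] + A[j,s] + gamma[i] * x[k] + eps[i,j,s,k]

with gene role i (target/reference), sample group j (case/control/standard),
sample s, dilution step x[k] (number of 2-fold dilutions), a sample random
effect A[j,s] ~ N(0, sigma_S^2) shared by all wells of a sample, and residual
noise eps ~ N(0, sigma_j^2) whose variance may differ by sample group.  The
slope gamma[i] is the inverse log2 amplification efficiency of gene i, so
AE[i] = 2**(1/gamma[i]).

The group means and the efficiencies are estimated simultaneously: fixed
effects are profiled out by generalized least squares at each value of the
variance parameters, and the profiled ML or REML criterion is maximised over
log standard deviations by L-BFGS-B with analytic gradients and a small set
of deterministic multi-starts.  This keeps every fit to a handful of
milliseconds, which matters because the bootstrap and the error-rate
simulations refit the model hundreds of thousands of times.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.linalg.lapack import dpotrf as _dpotrf, dpotrs as _dpotrs, dtrtrs as _dtrtrs

from .data import QpcrDataset, average_technical_replicates, validate_dataset

__all__ = [
    "ModelSpec",
    "FixedEffects",
    "FittedModel",
    "ConvergenceError",
    "fit_lmm",
    "marginal_criterion",
    "residual_df",
    "amplification_efficiency",
]

_LOG2PI = math.log(2.0 * math.pi)
_LOGSD_FLOOR = -15.0   # variance components may collapse to ~0 (sigma_S^2 boundary)
_LOGSD_CEIL = 8.0

EFFICIENCY_STRUCTURES = (
    "estimated_shared",    # one gamma per gene role, from the standard curve
    "estimated_by_group",  # gamma per (gene role, sample group)
    "fixed_known",         # user-supplied gammas, treated as exact
    "fixed_unity",         # gamma == 1; dilution data ignored (classical ddCq)
)


class ConvergenceError(RuntimeError):
    """The variance-parameter optimisation failed from every start."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixed-model variant.

    Parameters
    ----------
    efficiency_structure
        How amplification efficiencies enter the model; one of
        ``estimated_shared`` (default), ``estimated_by_group``,
        ``fixed_known`` or ``fixed_unity``.
    known_gamma
        For ``fixed_known``: map from gene role (or ``(role, group)``) to a
        strictly positive inverse log2-efficiency.
    residual_variance
        ``per_sample_group`` (a sigma_j^2 per group, the default) or
        ``pooled`` (one residual variance).
    sample_random_effect
        Include the per-sample random intercept A[j,s].
    replicate_random_effect
        Model technical replicates as a random effect (one level per well)
        instead of pre-averaging them; requires replicate_id in the data.
    criterion
        ``REML`` (default) or ``ML``.
    df_rule
        ``containment`` (n_obs - n_fixed - n_random_levels) or ``manual``
        with ``df_manual`` supplying the value.
    gamma_guard
        Estimated |gamma| below this triggers a near-zero-slope warning.
    """

    efficiency_structure: str = "estimated_shared"
    known_gamma: Mapping | None = None
    residual_variance: str = "per_sample_group"
    sample_random_effect: bool = True
    replicate_random_effect: bool = False
    criterion: str = "REML"
    df_rule: str = "containment"
    df_manual: float | None = None
    gamma_guard: float = 0.05

    def __post_init__(self):
        if self.efficiency_structure not in EFFICIENCY_STRUCTURES:
            raise ValueError(f"unknown efficiency_structure {self.efficiency_structure!r}")
        if self.residual_variance not in ("per_sample_group", "pooled"):
            raise ValueError(f"unknown residual_variance {self.residual_variance!r}")
        if self.criterion not in ("REML", "ML"):
            raise ValueError(f"criterion must be 'REML' or 'ML'")
        if self.df_rule not in ("containment", "manual"):
            raise ValueError("df_rule must be 'containment' or 'manual'")
        if self.df_rule == "manual" and self.df_manual is None:
            raise ValueError("df_rule='manual' requires df_manual")
        if self.efficiency_structure == "fixed_known":
            if not self.known_gamma or any(g <= 0 for g in self.known_gamma.values()):
                raise ValueError("fixed_known requires strictly positive known_gamma values")


@dataclass(frozen=True)
class FixedEffects:
    """Estimated group means and inverse log2-efficiencies.

    ``mu`` is keyed by ``(gene_role, sample_group)`` and includes the
    standard-curve intercepts as nuisance parameters when dilution data
    exist.  ``gamma`` is keyed by gene role under a shared efficiency
    structure and by ``(gene_role, sample_group)`` under the group-specific
    one; under fixed structures it holds the supplied constants.
    """

    mu: Mapping[tuple, float]
    gamma: Mapping = field(default_factory=dict)
    gamma_estimated: bool = True


@dataclass
class FittedModel:
    """Result of :func:`fit_lmm`.

    ``theta_cov`` is Var[theta_hat] = (X' V^-1 X)^-1 over ``labels`` (which
    include nuisance standard-curve intercepts and, when estimated, the
    gamma slopes).  ``df_residual`` is the containment (or manual) degrees
    of freedom used for all t-based inference downstream.
    """

    theta: FixedEffects
    labels: tuple
    theta_cov: np.ndarray
    sigma_S2: float
    sigma2: Mapping[str, float]
    sigma_rep2: float | None
    loglik: float
    n_obs: int
    n_fixed: int
    n_random_levels: int
    df_residual: float
    converged: bool
    spec: ModelSpec
    diagnostics: dict = field(default_factory=dict)
    _design: "object" = None
    _psi: np.ndarray | None = None

    def var_label(self, label) -> float:
        i = self.labels.index(label)
        return float(self.theta_cov[i, i])


# ---------------------------------------------------------------------------
# design assembly


class _Design:
    """Numeric design for one model variant; reusable with replaced responses."""

    def __init__(self, X, y, labels, re_terms, res_idx, res_groups, offset_gamma,
                 group_of_obs, meta):
        self.X = X                      # (n, p)
        self.y = y                      # (n,)
        self.labels = labels            # fixed-effect labels, order of X columns
        # re_terms: list of (name, Zidx (n,) int, n_levels, M (n,n) 0/1 float)
        self.re_terms = re_terms
        self.res_idx = res_idx          # (n,) int residual-variance group index
        self.res_groups = res_groups    # names of residual variance groups
        self.offset_gamma = offset_gamma  # dict of fixed gammas used as offset
        self.group_of_obs = group_of_obs  # (n,) sample_group strings (for bookkeeping)
        self.meta = meta                # misc (cells present, etc.)
        self.n, self.p = X.shape
        self.n_random_levels = sum(t[2] for t in re_terms)
        self.n_varpar = len(re_terms) + len(res_groups)
        self._I = np.eye(self.n)

    def with_y(self, y_new: np.ndarray) -> "_Design":
        d = _Design.__new__(_Design)
        d.__dict__ = {**self.__dict__, "y": np.asarray(y_new, float)}
        return d

    # -- criterion -----------------------------------------------------

    def _variances(self, psi):
        k = len(self.re_terms)
        re_var = np.exp(2.0 * psi[:k])
        res_var = np.exp(2.0 * psi[k:])
        return re_var, res_var

    def build_V(self, psi):
        re_var, res_var = self._variances(psi)
        V = np.diag(res_var[self.res_idx])
        for v, (_, _, _, M) in zip(re_var, self.re_terms):
            V += v * M
        return V

    def neg_criterion_grad(self, psi, reml: bool):
        """Negative profiled log-likelihood (ML) or REML criterion and its
        gradient with respect to the log standard deviations ``psi``.

        Implemented with direct LAPACK calls (Cholesky of the marginal
        covariance, triangular solves) because this function is evaluated
        millions of times inside the bootstrap and simulation loops.
        """
        n, p = self.n, self.p
        re_var, res_var = self._variances(psi)
        V = self.build_V(psi)
        L, info = _dpotrf(V, lower=1, clean=0, overwrite_a=1)
        if info != 0:
            return np.inf, np.zeros_like(psi)
        Xy = np.concatenate([self.X, self.y[:, None]], axis=1)
        A, _ = _dtrtrs(L, Xy, lower=1)
        Ax, ay = A[:, :p], A[:, p]
        XtViX = Ax.T @ Ax
        cF, info = _dpotrf(XtViX, lower=1, clean=0)
        if info != 0:
            return np.inf, np.zeros_like(psi)
        beta, _ = _dpotrs(cF, Ax.T @ ay, lower=1)
        w = ay - Ax @ beta                 # L^-1 (y - X beta)
        quad = float(w @ w)
        logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
        if reml:
            logdetF = 2.0 * float(np.sum(np.log(np.diag(cF))))
            crit = -0.5 * ((n - p) * _LOG2PI + logdetV + logdetF + quad)
        else:
            crit = -0.5 * (n * _LOG2PI + logdetV + quad)

        # gradient pieces (envelope theorem: beta is at its GLS optimum)
        Linv, _ = _dtrtrs(L, self._I, lower=1)
        Vinv = Linv.T @ Linv
        u = Linv.T @ w                    # V^-1 (y - X beta)
        if reml:
            W = Linv.T @ Ax               # V^-1 X
            G, _ = _dpotrs(cF, np.eye(p), lower=1)  # (X' V^-1 X)^-1
        grad = np.empty(self.n_varpar)
        k = len(self.re_terms)
        for m, (v, (_, zidx, _, M)) in enumerate(zip(re_var, self.re_terms)):
            # dV/dpsi = 2 v M
            tr = float(np.sum(Vinv * M))
            qd = float(u @ (M @ u))
            g = -0.5 * tr + 0.5 * qd
            if reml:
                g += 0.5 * float(np.sum(G * (W.T @ (M @ W))))
            grad[m] = 2.0 * v * g
        vdiag = np.diag(Vinv)
        u2 = u * u
        for j, v in enumerate(res_var):
            mask = self.res_idx == j
            g = -0.5 * float(np.sum(vdiag[mask])) + 0.5 * float(np.sum(u2[mask]))
            if reml:
                Wj = W[mask]
                g += 0.5 * float(np.sum(G * (Wj.T @ Wj)))
            grad[k + j] = 2.0 * v * g
        return -crit, -grad

    def gls(self, psi):
        """Fixed-effect estimates and covariance at variance parameters psi."""
        V = self.build_V(psi)
        L = np.linalg.cholesky(V)
        Xy = np.concatenate([self.X, self.y[:, None]], axis=1)
        A = solve_triangular(L, Xy, lower=True, check_finite=False)
        Ax, ay = A[:, : self.p], A[:, self.p]
        XtViX = Ax.T @ Ax
        cov = np.linalg.inv(XtViX)
        beta = cov @ (Ax.T @ ay)
        return beta, cov


def _build_design(ds: QpcrDataset, spec: ModelSpec) -> _Design:
    if not spec.replicate_random_effect:
        ds = average_technical_replicates(ds)
    df = ds.to_frame()

    if spec.efficiency_structure == "fixed_unity":
        # the classical (naive) ddCq ignores dilution data entirely
        df = df[(df.sample_group.isin(["case", "control"])) & (df.dilution_steps == 0)]
        df = df.reset_index(drop=True)
    if df.empty:
        raise ValueError("no usable records for this model specification")

    role = df.gene_role.to_numpy()
    group = df.sample_group.to_numpy()
    x = df.dilution_steps.to_numpy(float)
    y = df.cq.to_numpy(float).copy()
    n = len(df)

    # fixed-effect mean cells
    cells = sorted(set(zip(role, group)))
    labels: list[tuple] = [("mu",) + c for c in cells]
    cols = [np.asarray((role == c[0]) & (group == c[1]), float) for c in cells]

    offset_gamma = {}
    if spec.efficiency_structure == "estimated_shared":
        for r in sorted(set(role)):
            if np.any((role == r) & (x != 0)):
                labels.append(("gamma", r))
                cols.append(np.where(role == r, x, 0.0))
    elif spec.efficiency_structure == "estimated_by_group":
        for c in cells:
            sub = (role == c[0]) & (group == c[1])
            if np.any(sub & (x != 0)):
                labels.append(("gamma",) + c)
                cols.append(np.where(sub, x, 0.0))
    elif spec.efficiency_structure == "fixed_known":
        kg = dict(spec.known_gamma)
        for i in range(n):
            g = kg.get(role[i], kg.get((role[i], group[i])))
            if g is None:
                raise ValueError(f"no known gamma for gene role {role[i]!r}")
            y[i] -= g * x[i]
        offset_gamma = kg
    # fixed_unity: x == 0 everywhere after filtering; gamma implicitly 1

    X = np.column_stack(cols)

    # random-effect terms
    re_terms = []
    if spec.sample_random_effect:
        keys = list(zip(group, df.sample_id.to_numpy()))
        levels = sorted(set(keys))
        zidx = np.array([levels.index(k) for k in keys])
        M = np.asarray(zidx[:, None] == zidx[None, :], float)
        re_terms.append(("sample", zidx, len(levels), M))
    if spec.replicate_random_effect:
        keys = list(zip(df.gene_id, group, df.sample_id, x))
        levels = sorted(set(keys))
        zidx = np.array([levels.index(k) for k in keys])
        M = np.asarray(zidx[:, None] == zidx[None, :], float)
        re_terms.append(("replicate", zidx, len(levels), M))

    if spec.residual_variance == "per_sample_group":
        res_groups = sorted(set(group))
        res_idx = np.array([res_groups.index(g) for g in group])
    else:
        res_groups = ["pooled"]
        res_idx = np.zeros(n, int)

    meta = {"cells": cells, "structure": spec.efficiency_structure,
            "role": role, "group": group,
            "sample_id": df.sample_id.to_numpy(), "x": x}
    return _Design(X, y, tuple(labels), re_terms, res_idx, res_groups,
                   offset_gamma, group, meta)


# ---------------------------------------------------------------------------
# fitting


def _starts(design: _Design) -> list[np.ndarray]:
    """Deterministic multi-start points on the log-SD scale, anchored at the
    OLS residual scale of the data."""
    beta, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
    r = design.y - design.X @ beta
    dof = max(design.n - design.p, 1)
    base = 0.5 * math.log(max(float(r @ r) / dof, 1e-8))
    k = len(design.re_terms)
    s0 = np.full(design.n_varpar, base)
    starts = [s0]
    if k:
        s1 = s0.copy(); s1[:k] -= 1.5
        s2 = s0.copy(); s2[:k] += 1.0
        starts += [s1, s2]
    else:
        starts += [s0 - 1.0, s0 + 1.0]
    return starts


def _optimize(design: _Design, reml: bool, starts: Sequence[np.ndarray],
              gtol: float = 1e-8):
    from scipy.optimize import minimize

    bounds = [(_LOGSD_FLOOR, _LOGSD_CEIL)] * design.n_varpar
    best = None
    diag = {"n_starts": len(starts), "messages": []}
    for s in starts:
        res = minimize(design.neg_criterion_grad, s, args=(reml,), jac=True,
                       method="L-BFGS-B", bounds=bounds,
                       options={"gtol": gtol, "ftol": 1e-13, "maxiter": 200})
        diag["messages"].append(str(res.message))
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError(f"optimizer failed from all starts: {diag['messages']}")
    diag["final_grad_norm"] = float(np.max(np.abs(best.jac)))
    diag["success"] = bool(best.success)
    return best, diag


def fit_lmm(ds: QpcrDataset, spec: ModelSpec | None = None, *,
            start: np.ndarray | None = None, validate: bool = True) -> FittedModel:
    """Fit the mixed model to a single target/reference pair dataset.

    Technical replicates are averaged first unless the spec models them as a
    random effect.  ``start`` optionally warm-starts the variance-parameter
    search (used by the bootstrap); the deterministic multi-starts remain as
    a fallback.
    """
    spec = spec or ModelSpec()
    if validate:
        issues = validate_dataset(ds, spec)
        if issues:
            raise ValueError("dataset not analyzable under this spec: "
                             + "; ".join(issues))
    design = _build_design(ds, spec)
    return _fit_design(design, spec, start=start)


def _fit_design(design: _Design, spec: ModelSpec, *,
                start: np.ndarray | None = None,
                gtol: float = 1e-8) -> FittedModel:
    reml = spec.criterion == "REML"
    starts = [np.asarray(start, float)] if start is not None else _starts(design)
    try:
        best, diag = _optimize(design, reml, starts, gtol=gtol)
    except ConvergenceError:
        if start is None:
            raise
        best, diag = _optimize(design, reml, _starts(design), gtol=gtol)
    psi = best.x
    beta, cov = design.gls(psi)

    k = len(design.re_terms)
    re_var, res_var = design._variances(psi)
    sigma_S2 = 0.0
    sigma_rep2 = None
    for v, term in zip(re_var, design.re_terms):
        if term[0] == "sample":
            sigma_S2 = float(v)
        elif term[0] == "replicate":
            sigma_rep2 = float(v)
    if k and np.any(psi[:k] <= _LOGSD_FLOOR + 1e-6):
        warnings.warn("a random-effect variance estimate is at the zero boundary",
                      RuntimeWarning, stacklevel=2)
        diag["boundary"] = True
    sigma2 = {g: float(v) for g, v in zip(design.res_groups, res_var)}

    mu = {}
    gamma = {}
    for lab, b in zip(design.labels, beta):
        if lab[0] == "mu":
            mu[lab[1:]] = float(b)
        else:
            key = lab[1] if len(lab) == 2 else lab[1:]
            gamma[key] = float(b)
    gamma_estimated = spec.efficiency_structure in ("estimated_shared",
                                                    "estimated_by_group")
    if spec.efficiency_structure == "fixed_unity":
        gamma = {r: 1.0 for r in ("target", "reference")}
    elif spec.efficiency_structure == "fixed_known":
        gamma = dict(spec.known_gamma)
    if gamma_estimated:
        for key, g in gamma.items():
            if abs(g) < spec.gamma_guard:
                warnings.warn(
                    f"estimated gamma for {key} is {g:.4g}, inside the near-zero "
                    "guard band; efficiency-corrected quantities are unstable",
                    RuntimeWarning, stacklevel=2)

    theta = FixedEffects(mu=mu, gamma=gamma, gamma_estimated=gamma_estimated)
    n_fixed = design.p
    df_res = residual_df(design.n, n_fixed, design.n_random_levels,
                         rule=spec.df_rule, manual=spec.df_manual)
    return FittedModel(
        theta=theta, labels=design.labels, theta_cov=cov,
        sigma_S2=sigma_S2, sigma2=sigma2, sigma_rep2=sigma_rep2,
        loglik=-float(best.fun), n_obs=design.n, n_fixed=n_fixed,
        n_random_levels=design.n_random_levels, df_residual=df_res,
        converged=bool(diag.get("success", False)), spec=spec,
        diagnostics=diag, _design=design, _psi=psi.copy(),
    )


# ---------------------------------------------------------------------------
# explicit criterion evaluation (testing / diagnostics)


def marginal_criterion(ds: QpcrDataset, spec: ModelSpec,
                       mu: Mapping, gamma: Mapping | None,
                       sigma_S2: float, sigma2, sigma_rep2: float | None = None,
                       criterion: str | None = None) -> float:
    """Exact marginal Gaussian criterion at user-supplied parameter values.

    For ``criterion='ML'`` (the default) this is the joint log-density of the
    observed Cq vector under N(X theta, V) with V assembled from the supplied
    variance components; for ``'REML'`` it is the restricted likelihood, in
    which the fixed effects are profiled out and the ``mu``/``gamma`` values
    only fix the mean structure, not the criterion value.  Deterministic.
    """
    criterion = criterion or "ML"
    design = _build_design(ds, spec)
    # assemble psi on the log-SD scale
    k = len(design.re_terms)
    psi = np.empty(design.n_varpar)
    for m, term in enumerate(design.re_terms):
        v = sigma_S2 if term[0] == "sample" else (sigma_rep2 or 0.0)
        psi[m] = 0.5 * math.log(max(v, 1e-300)) if v > 0 else _LOGSD_FLOOR * 4
    if isinstance(sigma2, Mapping):
        res = [sigma2[g] for g in design.res_groups]
    else:
        res = [float(sigma2)] * len(design.res_groups)
    if any(s <= 0 for s in res):
        raise ValueError("residual variances must be strictly positive")
    psi[k:] = [0.5 * math.log(s) for s in res]

    V = design.build_V(psi)
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular marginal covariance")
    if criterion == "REML":
        nc, _ = design.neg_criterion_grad(psi, reml=True)
        return -float(nc)
    # build the mean from supplied fixed effects
    theta = np.empty(design.p)
    for i, lab in enumerate(design.labels):
        if lab[0] == "mu":
            theta[i] = mu[lab[1:]]
        else:
            key = lab[1] if len(lab) == 2 else lab[1:]
            theta[i] = gamma[key]
    r = design.y - design.X @ theta
    u = np.linalg.solve(V, r)
    return -0.5 * (design.n * _LOG2PI + logdetV + float(r @ u))


def residual_df(n_obs: int, n_fixed: int, n_random_levels: int,
                rule: str = "containment", manual: float | None = None) -> float:
    """Degrees of freedom for t-based inference.

    The containment rule eta = n_obs - n_fixed - n_random_levels is exact in
    the balanced designs this model targets; ``manual`` overrides it for
    designs where a different convention is wanted.
    """
    if rule == "manual":
        if manual is None or manual <= 0:
            raise ValueError("manual df rule requires a positive value")
        return float(manual)
    eta = n_obs - n_fixed - n_random_levels
    if eta <= 0:
        raise ValueError(
            f"containment degrees of freedom nonpositive ({eta}); "
            "supply a manual df for this design")
    return float(eta)


def amplification_efficiency(gamma: float) -> float:
    """Per-cycle amplification factor AE = 2**(1/gamma).

    gamma is the standard-curve slope of Cq on the number of 2-fold
    dilutions; gamma = 1 is perfect doubling (AE = 2).
    """
    if gamma == 0:
        raise ValueError("gamma = 0 has no defined amplification efficiency")
    if gamma < 0:
        warnings.warn("gamma <= 0 implies an amplification efficiency below 1, "
                      "which is physically suspect", RuntimeWarning, stacklevel=2)
    return float(2.0 ** (1.0 / gamma))
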