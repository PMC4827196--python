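"""Bootstrap inference for the delta-delta Cq.

Two resampling schemes are provided for the standard paired case/control
design with a standard-curve dilution series:

* **Nonparametric (block + residual).**  Within the case group and within
  the control group, sample identifiers are drawn with replacement and each
  drawn sample carries its matched target AND reference wells together, so
  the within-sample dependence induced by the shared random effect is
  preserved.  The dilution series has a single well per step, so it is
  rebuilt by residual resampling: per gene, an ordinary least-squares line
  of Cq on dilution steps is fitted, its centered residuals are resampled
  with replacement, and added back to the fitted line.
* **Parametric.**  New sample random effects and residual noise are drawn
  from the fitted variance components and added to the fitted means.

Each resampled dataset is refitted with the full mixed model (warm-started
at the original variance-parameter optimum) and the efficiency-corrected
point estimate recorded.  Standard errors, percentile confidence intervals
and an add-one sign-count p-value are read off the resulting distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .data import CqRecord, QpcrDataset, average_technical_replicates
from .inference import DdcqResult, ddcq_contrast, fold_change
from .lmm import ConvergenceError, ModelSpec, _build_design, _fit_design, fit_lmm

__all__ = [
    "BootstrapDistribution",
    "bootstrap_distribution",
    "parametric_bootstrap",
    "bootstrap_summary",
    "resample_dataset",
]


@dataclass(frozen=True)
class BootstrapDistribution:
    """Bootstrap draws of the ddCq estimate."""

    draws: np.ndarray          # successful draws only, length B - n_failed
    B: int
    scheme: str                # "nonparametric" | "parametric"
    seed: int | None
    n_failed: int = 0

    def __post_init__(self):
        if self.n_failed / max(self.B, 1) >= 0.05:
            warnings.warn(f"{self.n_failed}/{self.B} bootstrap refits failed",
                          RuntimeWarning, stacklevel=3)


class _BootPrep:
    """Shared preparation for the nonparametric scheme: matched-pair blocks,
    per-gene standard-curve regressions, and a reusable template design."""

    def __init__(self, ds: QpcrDataset, spec: ModelSpec):
        if spec.replicate_random_effect:
            raise ValueError("the bootstrap operates on replicate-averaged data")
        ds = average_technical_replicates(ds)
        df = ds.to_frame()

        self.spec = spec
        self.roles = ("target", "reference")
        # matched case/control pairs at x = 0
        self.pairs = {}
        for group in ("case", "control"):
            sub = df[(df.sample_group == group) & (df.dilution_steps == 0)]
            ids = sorted(sub.sample_id.unique())
            vals = np.empty((len(ids), 2))
            for a, sid in enumerate(ids):
                for b, role in enumerate(self.roles):
                    row = sub[(sub.sample_id == sid) & (sub.gene_role == role)]
                    if len(row) != 1:
                        raise ValueError(
                            f"sample {sid!r} ({group}) must have exactly one "
                            f"{role} record for the block bootstrap")
                    vals[a, b] = float(row.cq.iloc[0])
            self.pairs[group] = (ids, vals)

        # per-gene simple linear regression on the standard curve
        self.std = {}
        std = df[df.sample_group == "standard"]
        self.std_sample = std.sample_id.iloc[0] if len(std) else "std"
        for role in self.roles:
            sub = std[std.gene_role == role].sort_values("dilution_steps")
            if sub.empty:
                continue
            x = sub.dilution_steps.to_numpy(float)
            y = sub.cq.to_numpy(float)
            gid = sub.gene_id.iloc[0]
            slope, icept = np.polyfit(x, y, 1)
            fitted = icept + slope * x
            resid = y - fitted
            resid = resid - resid.mean()
            self.std[role] = dict(x=x, fitted=fitted, resid=resid, gene=gid)

        # gene ids for rebuilding record-level resamples
        self.gene_of_role = {
            role: df[df.gene_role == role].gene_id.iloc[0] for role in self.roles
        }

        # template dataset with slot sample ids; design built once
        template = self._records_from(
            {g: (np.arange(len(self.pairs[g][0])),) for g in self.pairs},
            {r: np.arange(len(self.std[r]["x"])) for r in self.std},
        )
        tds = QpcrDataset(tuple(template), name="bootstrap-template")
        self.design = _build_design(tds, spec)
        # row lookup: (group, sample_id, role) -> design row
        m = self.design.meta
        key = list(zip(m["group"], m["sample_id"], m["role"], m["x"]))
        self.rows = {k: i for i, k in enumerate(key)}
        self.row_sets = {}
        for group in ("case", "control"):
            n = len(self.pairs[group][0])
            for bi, role in enumerate(self.roles):
                idx = np.array([self.rows[(group, f"{group}_{i}", role, 0.0)]
                                for i in range(n)])
                self.row_sets[(group, role)] = idx
        for role, d in self.std.items():
            idx = np.array([self.rows[("standard", self.std_sample, role, xv)]
                            for xv in d["x"]])
            self.row_sets[("standard", role)] = idx

    # the rng draw order below is the scheme's contract: case choices, control
    # choices, then per-role residual indices with roles in sorted order
    def draw_indices(self, rng):
        out = {}
        for group in ("case", "control"):
            n = len(self.pairs[group][0])
            out[group] = rng.integers(0, n, size=n)
        for role in sorted(self.std):
            K = len(self.std[role]["x"])
            out[("std", role)] = rng.integers(0, K, size=K)
        return out

    def fill_y(self, idx) -> np.ndarray:
        y = np.empty(self.design.n)
        for group in ("case", "control"):
            _, vals = self.pairs[group]
            choice = idx[group]
            for bi, role in enumerate(self.roles):
                y[self.row_sets[(group, role)]] = vals[choice, bi]
        for role, d in self.std.items():
            y[self.row_sets[("standard", role)]] = (
                d["fitted"] + d["resid"][idx[("std", role)]])
        return y

    def _records_from(self, group_slots, std_slots):
        """Placeholder records defining the template shapes (cq values are
        overwritten per replicate)."""
        recs = []
        for group, (slots,) in group_slots.items():
            for i in slots:
                for role in self.roles:
                    recs.append(CqRecord(
                        gene_id=self.gene_of_role[role], gene_role=role,
                        sample_group=group, sample_id=f"{group}_{i}",
                        dilution_steps=0.0, cq=0.0))
        for role, slots in std_slots.items():
            d = self.std[role]
            for k in slots:
                recs.append(CqRecord(
                    gene_id=d["gene"], gene_role=role, sample_group="standard",
                    sample_id=str(self.std_sample),
                    dilution_steps=float(d["x"][k]), cq=0.0))
        return recs


def resample_dataset(ds: QpcrDataset, spec: ModelSpec, rng) -> QpcrDataset:
    """One nonparametric block+residual resample, materialised as a dataset.

    Drawn sample ids become fresh slot identities (a sample drawn twice
    contributes two independent random-effect levels), and each slot carries
    its matched target and reference Cq values together.
    """
    prep = _BootPrep(ds, spec)
    idx = prep.draw_indices(rng)
    recs = []
    for group in ("case", "control"):
        _, vals = prep.pairs[group]
        for i, ch in enumerate(idx[group]):
            for bi, role in enumerate(prep.roles):
                recs.append(CqRecord(
                    gene_id=prep.gene_of_role[role], gene_role=role,
                    sample_group=group, sample_id=f"{group}_{i}",
                    dilution_steps=0.0, cq=float(vals[ch, bi])))
    for role in sorted(prep.std):
        d = prep.std[role]
        ystar = d["fitted"] + d["resid"][idx[("std", role)]]
        for k, xv in enumerate(d["x"]):
            recs.append(CqRecord(
                gene_id=d["gene"], gene_role=role, sample_group="standard",
                sample_id=str(prep.std_sample), dilution_steps=float(xv),
                cq=float(ystar[k])))
    return QpcrDataset(tuple(recs), name=f"{ds.name}:resample")


def bootstrap_distribution(ds: QpcrDataset, spec: ModelSpec | None = None,
                           B: int = 2000, seed: int | None = None,
                           rng=None) -> BootstrapDistribution:
    """Nonparametric block+residual bootstrap distribution of the
    efficiency-corrected ddCq estimate.

    Each of the ``B`` resamples preserves group sizes and target/reference
    pairing; the standard curve is rebuilt by residual resampling around its
    per-gene regression line.  Every resample is refitted with the full
    model, warm-started at the original fit's variance parameters.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    spec = spec or ModelSpec()
    rng = np.random.default_rng(seed) if rng is None else rng
    prep = _BootPrep(ds, spec)
    fit0 = fit_lmm(ds, spec)
    psi0 = fit0._psi

    draws = np.empty(B)
    n_failed = 0
    k = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for b in range(B):
            idx = prep.draw_indices(rng)
            y = prep.fill_y(idx)
            try:
                fit = _fit_design(prep.design.with_y(y), spec, start=psi0,
                                  gtol=1e-5)
                draws[k] = ddcq_contrast(fit.theta, spec.gamma_guard)
                k += 1
            except (ConvergenceError, np.linalg.LinAlgError, ZeroDivisionError):
                n_failed += 1
    return BootstrapDistribution(draws=draws[:k], B=B, scheme="nonparametric",
                                 seed=seed, n_failed=n_failed)


def parametric_bootstrap(fit, B: int = 2000, seed: int | None = None,
                         rng=None) -> BootstrapDistribution:
    """Parametric bootstrap: simulate new random effects and residual noise
    from the fitted variance components, add them to the fitted means, refit
    and record the efficiency-corrected estimate."""
    if B < 100:
        raise ValueError("B must be at least 100")
    if not fit.converged and fit._psi is None:
        raise ValueError("parametric bootstrap needs a converged fit")
    rng = np.random.default_rng(seed) if rng is None else rng
    design = fit._design
    spec = fit.spec
    beta, _ = design.gls(fit._psi)
    mean = design.X @ beta
    re_var, res_var = design._variances(fit._psi)
    res_sd_obs = np.sqrt(res_var[design.res_idx])

    draws = np.empty(B)
    n_failed = 0
    k = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for b in range(B):
            y = mean.copy()
            for v, (_, zidx, nlev, _) in zip(re_var, design.re_terms):
                a = rng.normal(0.0, math.sqrt(v), size=nlev)
                y += a[zidx]
            y += rng.normal(0.0, 1.0, size=design.n) * res_sd_obs
            try:
                f = _fit_design(design.with_y(y), spec, start=fit._psi,
                                gtol=1e-5)
                draws[k] = ddcq_contrast(f.theta, spec.gamma_guard)
                k += 1
            except (ConvergenceError, np.linalg.LinAlgError, ZeroDivisionError):
                n_failed += 1
    return BootstrapDistribution(draws=draws[:k], B=B, scheme="parametric",
                                 seed=seed, n_failed=n_failed)


def percentile(draws: np.ndarray, q: float) -> float:
    """Inverse-ECDF percentile: the order statistic at ceiling(q*n)."""
    s = np.sort(draws)
    n = len(s)
    i = min(max(int(math.ceil(q * n)), 1), n)
    return float(s[i - 1])


def bootstrap_p_value(draws: np.ndarray) -> float:
    """Two-sided add-one sign-count p-value for H0: ddCq = 0,
    p = 2 (1 + min(#{d <= 0}, #{d >= 0})) / (n + 1), capped at 1."""
    n = len(draws)
    n_le = int(np.sum(draws <= 0))
    n_ge = int(np.sum(draws >= 0))
    return min(1.0, 2.0 * (1 + min(n_le, n_ge)) / (n + 1))


def bootstrap_summary(dist: BootstrapDistribution, level: float = 0.05,
                      label: str = "") -> DdcqResult:
    """Summarise a bootstrap distribution: mean estimate, sample-SD standard
    error, percentile confidence interval and sign-count p-value."""
    draws = np.asarray(dist.draws, float)
    if len(draws) < 100:
        raise ValueError("need at least 100 successful bootstrap draws")
    est = float(draws.mean())
    se = float(draws.std(ddof=1))
    lo = percentile(draws, level / 2.0)
    hi = percentile(draws, 1.0 - level / 2.0)
    method = "bootstrap_np" if dist.scheme == "nonparametric" else "bootstrap_param"
    return DdcqResult(
        method=method, estimate=est, se=se, t_value=math.nan, df=math.nan,
        p_value=bootstrap_p_value(draws), ci_lower=lo, ci_upper=hi,
        fold_change=fold_change(est), level=level, B=dist.B, seed=dist.seed,
        label=label,
    )
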