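"""Mixed-model engine tests, including brute-force oracles."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

from ddcq import (
    CqRecord,
    ModelSpec,
    QpcrDataset,
    amplification_efficiency,
    ddcq_contrast,
    fit_lmm,
    marginal_criterion,
    residual_df,
)
from ddcq.lmm import _build_design
from conftest import make_dataset


# ---------------------------------------------------------------------------
# dense multivariate-normal oracle (independent of the package's linear algebra)


def dense_loglik(ds, mu, gamma, sigma_S2, sigma2):
    """Joint Gaussian log-density computed the slow, obvious way."""
    from ddcq.data import average_technical_replicates

    recs = average_technical_replicates(ds).records
    n = len(recs)
    mean = np.array([mu[(r.gene_role, r.sample_group)]
                     + gamma[r.gene_role] * r.dilution_steps for r in recs])
    y = np.array([r.cq for r in recs])
    V = np.zeros((n, n))
    for i, a in enumerate(recs):
        for j, b in enumerate(recs):
            if (a.sample_group, a.sample_id) == (b.sample_group, b.sample_id):
                V[i, j] += sigma_S2
            if i == j:
                s2 = sigma2[a.sample_group] if isinstance(sigma2, dict) else sigma2
                V[i, j] += s2
    return float(stats.multivariate_normal.logpdf(y, mean=mean, cov=V))


def tiny_dataset(seed=0, **kw):
    kw.setdefault("n_per_group", 2)
    kw.setdefault("K", 2)
    return make_dataset(seed=seed, **kw)  # 12 observations


UNIT_MU = {(r, g): 25.0 for r in ("target", "reference")
           for g in ("case", "control", "standard")}
UNIT_GAMMA = {"target": 1.25, "reference": 1.0 / 0.95}


def test_marginal_criterion_matches_dense_oracle():
    ds = tiny_dataset(seed=10)
    spec = ModelSpec()  # per-group residual variances
    for mu_shift, s_S2, s2 in [(0.0, 1.0, {"case": 1.0, "control": 0.7, "standard": 1.3}),
                               (1.5, 0.25, {"case": 2.0, "control": 0.5, "standard": 1.0})]:
        mu = {k: v + mu_shift for k, v in UNIT_MU.items()}
        got = marginal_criterion(ds, spec, mu, UNIT_GAMMA, s_S2, s2)
        want = dense_loglik(ds, mu, UNIT_GAMMA, s_S2, s2)
        assert got == pytest.approx(want, abs=1e-10)


def test_marginal_criterion_translation_invariance():
    ds = tiny_dataset(seed=11)
    spec = ModelSpec(residual_variance="pooled")
    base = marginal_criterion(ds, spec, UNIT_MU, UNIT_GAMMA, 1.0, 1.0)
    c = 7.3
    shifted_ds = QpcrDataset(
        tuple(CqRecord(r.gene_id, r.gene_role, r.sample_group, r.sample_id,
                       r.dilution_steps, r.cq + c) for r in ds.records),
        pairing=dict(ds.pairing))
    shifted_mu = {k: v + c for k, v in UNIT_MU.items()}
    moved = marginal_criterion(shifted_ds, spec, shifted_mu, UNIT_GAMMA, 1.0, 1.0)
    assert moved == pytest.approx(base, abs=1e-10)


def test_marginal_criterion_independence_limit():
    # sigma_S^2 = 0: the joint density factorises into univariate normals
    ds = tiny_dataset(seed=12)
    spec = ModelSpec(residual_variance="pooled")
    got = marginal_criterion(ds, spec, UNIT_MU, UNIT_GAMMA, 0.0, 0.8)
    want = sum(
        stats.norm.logpdf(r.cq,
                          UNIT_MU[(r.gene_role, r.sample_group)]
                          + UNIT_GAMMA[r.gene_role] * r.dilution_steps,
                          math.sqrt(0.8))
        for r in ds.records)
    assert got == pytest.approx(want, abs=1e-8)


def test_reml_criterion_ignores_fixed_effects():
    ds = tiny_dataset(seed=13, K=3)  # 14 observations, df = 1
    spec = ModelSpec()  # REML
    fit = fit_lmm(ds, spec, validate=False)  # tiny 2-step curve, exactness only
    val = marginal_criterion(ds, spec, UNIT_MU, UNIT_GAMMA,
                             fit.sigma_S2, fit.sigma2, criterion="REML")
    assert val == pytest.approx(fit.loglik, abs=1e-8)
    # and supplying different fixed effects changes nothing
    other_mu = {k: v + 3.0 for k, v in UNIT_MU.items()}
    assert marginal_criterion(ds, spec, other_mu, UNIT_GAMMA,
                              fit.sigma_S2, fit.sigma2,
                              criterion="REML") == pytest.approx(val, abs=1e-12)


def test_fit_beats_random_parameter_draws():
    # no random draw of (mu, gamma, variances) may beat the optimizer
    ds = tiny_dataset(seed=14, K=3)  # 14 observations
    spec = ModelSpec(criterion="ML", residual_variance="pooled")
    fit = fit_lmm(ds, spec, validate=False)
    rng = np.random.default_rng(99)
    recs = ds.records
    n = len(recs)
    y = np.array([r.cq for r in recs])
    same = np.array([[(a.sample_group, a.sample_id) == (b.sample_group, b.sample_id)
                      for b in recs] for a in recs], float)
    cells = sorted({(r.gene_role, r.sample_group) for r in recs})
    cell_idx = np.array([cells.index((r.gene_role, r.sample_group)) for r in recs])
    is_tgt = np.array([r.gene_role == "target" for r in recs])
    x = np.array([r.dilution_steps for r in recs])
    best = -np.inf
    for _ in range(10_000):
        mu = 25.0 + rng.uniform(-3, 3, size=len(cells))
        g_t, g_r = rng.uniform(0.3, 2.5, size=2)
        s_S2 = rng.uniform(0.0, 4.0)
        s2 = rng.uniform(0.05, 4.0)
        mean = mu[cell_idx] + np.where(is_tgt, g_t, g_r) * x
        V = s_S2 * same + s2 * np.eye(n)
        sign, logdet = np.linalg.slogdet(V)
        r = y - mean
        ll = -0.5 * (n * math.log(2 * math.pi) + logdet
                     + float(r @ np.linalg.solve(V, r)))
        best = max(best, ll)
    assert fit.loglik >= best - 1e-4


def test_fit_loglik_matches_dense_oracle_at_estimates():
    ds = tiny_dataset(seed=15, K=3)
    spec = ModelSpec(criterion="ML", residual_variance="pooled")
    fit = fit_lmm(ds, spec, validate=False)
    want = dense_loglik(ds, fit.theta.mu, fit.theta.gamma,
                        fit.sigma_S2, fit.sigma2["pooled"])
    assert fit.loglik == pytest.approx(want, abs=1e-6)


def test_analytic_gradient_matches_finite_differences():
    ds = make_dataset(seed=16, n_per_group=3, K=4)
    for crit in ("ML", "REML"):
        spec = ModelSpec(criterion=crit)
        design = _build_design(ds, spec)
        psi = np.array([0.1, -0.3, 0.2, -0.1, 0.05])[: design.n_varpar]
        _, grad = design.neg_criterion_grad(psi.copy(), reml=(crit == "REML"))
        h = 1e-6
        for m in range(design.n_varpar):
            up, dn = psi.copy(), psi.copy()
            up[m] += h
            dn[m] -= h
            fu, _ = design.neg_criterion_grad(up, reml=(crit == "REML"))
            fd, _ = design.neg_criterion_grad(dn, reml=(crit == "REML"))
            num = (fu - fd) / (2 * h)
            assert grad[m] == pytest.approx(num, rel=1e-6, abs=1e-8)


def test_fixed_unity_recovers_cell_means():
    ds = make_dataset(seed=17)
    fit = fit_lmm(ds, ModelSpec(efficiency_structure="fixed_unity"))
    df = ds.to_frame()
    cc = df[df.sample_group.isin(["case", "control"])]
    for (role, group), m in fit.theta.mu.items():
        cell = cc[(cc.gene_role == role) & (cc.sample_group == group)]
        assert m == pytest.approx(cell.cq.mean(), abs=1e-8)
    assert fit.theta.gamma == {"target": 1.0, "reference": 1.0}
    # dilution data are genuinely ignored: no standard-group observations used
    assert fit.n_obs == len(cc)


def test_ml_and_reml_agree_on_fixed_effects_when_balanced():
    ds = make_dataset(seed=18)
    f_ml = fit_lmm(ds, ModelSpec(criterion="ML"))
    f_reml = fit_lmm(ds, ModelSpec(criterion="REML"))
    for key in f_ml.theta.mu:
        assert f_ml.theta.mu[key] == pytest.approx(f_reml.theta.mu[key], abs=1e-6)
    for key in f_ml.theta.gamma:
        assert f_ml.theta.gamma[key] == pytest.approx(f_reml.theta.gamma[key], abs=1e-6)


def test_scale_equivariance():
    ds = make_dataset(seed=19)
    c = 3.0
    scaled = QpcrDataset(
        tuple(CqRecord(r.gene_id, r.gene_role, r.sample_group, r.sample_id,
                       r.dilution_steps, c * r.cq) for r in ds.records),
        pairing=dict(ds.pairing))
    f1 = fit_lmm(ds)
    f2 = fit_lmm(scaled)
    for key in f1.theta.mu:
        assert f2.theta.mu[key] == pytest.approx(c * f1.theta.mu[key], rel=1e-6)
    for key in f1.theta.gamma:
        assert f2.theta.gamma[key] == pytest.approx(c * f1.theta.gamma[key], rel=1e-6)
    assert f2.sigma_S2 == pytest.approx(c**2 * f1.sigma_S2, rel=1e-4, abs=1e-8)
    # the ddCq contrast (ratio of means to slopes) is scale invariant
    assert ddcq_contrast(f2.theta) == pytest.approx(ddcq_contrast(f1.theta), rel=1e-6)


def test_parameter_recovery():
    # average estimates over R datasets: each label's mean must sit within
    # 3 Monte Carlo standard errors (mean reported se / sqrt(R)) of the truth
    R = 20
    fits = [fit_lmm(make_dataset(seed=300 + i, n_per_group=10, K=8))
            for i in range(R)]
    truth_gamma = {"target": 1.0 / 0.80, "reference": 1.0 / 0.95}
    for lab in fits[0].labels:
        want = 25.0 if lab[0] == "mu" else truth_gamma[lab[1]]
        ests = [f.theta.mu.get(lab[1:], f.theta.gamma.get(lab[1])) for f in fits]
        mc_se = np.mean([math.sqrt(f.var_label(lab)) for f in fits]) / math.sqrt(R)
        assert abs(np.mean(ests) - want) <= 3 * mc_se, (lab, np.mean(ests), want)
    assert 0.3 < np.mean([f.sigma_S2 for f in fits]) < 3.0
    assert 0.3 < np.mean([np.mean(list(f.sigma2.values())) for f in fits]) < 3.0


def test_noiseless_recovery_is_exact():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ds = make_dataset(seed=21, hypothesis="alternative", sigma=0.0, sigma_S=0.0)
        fit = fit_lmm(ds, ModelSpec(criterion="ML", residual_variance="pooled"))
        assert ddcq_contrast(fit.theta) == pytest.approx(10.0 / 9.0, abs=1e-8)
        assert fit.theta.gamma["target"] == pytest.approx(1.25, abs=1e-8)


def test_fixed_known_uses_supplied_slopes():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ds = make_dataset(seed=22, hypothesis="alternative", sigma=0.0, sigma_S=0.0)
        spec = ModelSpec(efficiency_structure="fixed_known",
                         known_gamma={"target": 1.25, "reference": 1.0 / 0.95})
        fit = fit_lmm(ds, spec)
    assert fit.theta.gamma_estimated is False
    assert all(lab[0] == "mu" for lab in fit.labels)  # no gamma columns
    assert ddcq_contrast(fit.theta) == pytest.approx(10.0 / 9.0, abs=1e-8)


def test_group_specific_efficiencies():
    # a design that dilutes the biological samples themselves
    rng = np.random.default_rng(23)
    gam = {("target", "case"): 1.30, ("target", "control"): 1.20,
           ("reference", "case"): 1.05, ("reference", "control"): 1.00}
    recs = []
    for group in ("case", "control"):
        for s in range(6):
            A = rng.normal(0, 0.3)
            x = float(s)  # dilutions 0..5 across samples
            for role in ("target", "reference"):
                cq = 25.0 + gam[(role, group)] * x + A + rng.normal(0, 0.05)
                recs.append(CqRecord(role[:3].upper(), role, group,
                                     f"{group}_{s}", x, cq))
    ds = QpcrDataset(tuple(recs), pairing={"TAR": "REF"})
    spec = ModelSpec(efficiency_structure="estimated_by_group")
    from ddcq import validate_dataset
    assert validate_dataset(ds, spec) == []
    fit = fit_lmm(ds, spec)
    assert fit.n_fixed == 8
    assert fit.df_residual == 4  # 24 obs - 8 fixed - 12 sample levels
    for cell, want in gam.items():
        assert fit.theta.gamma[cell] == pytest.approx(want, abs=0.1)


def test_variance_boundary_collapses_to_zero():
    # sample means exactly constant: the random-effect variance goes to ~0
    recs = []
    for group in ("case", "control"):
        for s in range(4):
            e = 0.5 if s % 2 == 0 else -0.5
            recs.append(CqRecord("TAR", "target", group, f"{group}_{s}", 0.0, 25.0 + e))
            recs.append(CqRecord("REF", "reference", group, f"{group}_{s}", 0.0, 25.0 - e))
    for role, gid in (("target", "TAR"), ("reference", "REF")):
        for k in range(1, 5):
            recs.append(CqRecord(gid, role, "standard", "std", float(k),
                                 25.0 + 1.1 * k + (0.2 if k % 2 else -0.2)))
    ds = QpcrDataset(tuple(recs), pairing={"TAR": "REF"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = fit_lmm(ds, ModelSpec(criterion="ML", residual_variance="pooled"))
    assert fit.sigma_S2 < 1e-4


def test_replicate_preaveraging_equivalence():
    ds = make_dataset(seed=24)
    jittered = []
    for r in ds.records:
        for rep, d in (("a", 0.2), ("b", -0.2)):
            jittered.append(CqRecord(r.gene_id, r.gene_role, r.sample_group,
                                     r.sample_id, r.dilution_steps, r.cq + d,
                                     replicate_id=rep))
    dsr = QpcrDataset(tuple(jittered), pairing=dict(ds.pairing))
    f1 = fit_lmm(ds)
    f2 = fit_lmm(dsr)  # replicates averaged internally; means recover ds
    for key in f1.theta.mu:
        assert f2.theta.mu[key] == pytest.approx(f1.theta.mu[key], abs=1e-6)


def test_fit_rejects_unanalyzable_dataset():
    ds = make_dataset(seed=25)
    no_std = QpcrDataset(tuple(r for r in ds.records if r.sample_group != "standard"),
                         pairing=dict(ds.pairing))
    with pytest.raises(ValueError, match="not analyzable"):
        fit_lmm(no_std, ModelSpec())


def test_residual_df_containment_and_manual():
    assert residual_df(46, 8, 17) == 21.0   # large paired-cohort shape
    assert residual_df(24, 8, 12) == 4.0    # diluted-samples shape
    assert residual_df(36, 8, 13) == 15.0   # benchmark simulation shape
    assert residual_df(20, 4, 0) == 16.0    # no random effects: N - p
    assert residual_df(10, 4, 0, rule="manual", manual=7.5) == 7.5
    with pytest.raises(ValueError):
        residual_df(10, 8, 5)
    with pytest.raises(ValueError):
        residual_df(10, 2, 0, rule="manual", manual=None)


def test_simulated_design_df():
    fit = fit_lmm(make_dataset(seed=26))
    # 36 obs, 6 mu + 2 gamma fixed, 13 random-effect levels
    assert fit.n_obs == 36
    assert fit.n_fixed == 8
    assert fit.n_random_levels == 13
    assert fit.df_residual == 15.0


def test_amplification_efficiency():
    assert amplification_efficiency(1.0) == pytest.approx(2.0)
    assert amplification_efficiency(1.25) == pytest.approx(2.0 ** 0.8)
    assert amplification_efficiency(2.0) == pytest.approx(math.sqrt(2.0))
    with pytest.raises(ValueError):
        amplification_efficiency(0.0)
    with pytest.warns(RuntimeWarning):
        assert amplification_efficiency(-1.0) == pytest.approx(0.5)


def test_gamma_precision_improves_with_more_dilutions():
    var4, var9 = [], []
    for seed in range(20):
        f4 = fit_lmm(make_dataset(seed=100 + seed, K=4))
        f9 = fit_lmm(make_dataset(seed=100 + seed, K=9))
        var4.append(f4.var_label(("gamma", "target")))
        var9.append(f9.var_label(("gamma", "target")))
    assert np.mean(var9) < np.mean(var4)


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(efficiency_structure="banana")
    with pytest.raises(ValueError):
        ModelSpec(residual_variance="heteroskedastic")
    with pytest.raises(ValueError):
        ModelSpec(criterion="MAP")
    with pytest.raises(ValueError):
        ModelSpec(df_rule="manual")  # needs df_manual
    with pytest.raises(ValueError):
        ModelSpec(efficiency_structure="fixed_known")  # needs known_gamma
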