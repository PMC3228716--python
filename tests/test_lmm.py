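"""Mixed-model engine: closed-form oracles, the full-covariance
likelihood oracle, root-embedding equivalence and inference helpers."""

import numpy as np
import pytest
from scipy import stats

from ryeassoc.lmm import (
    ModelSpec,
    RandomBlock,
    direct_loglik,
    fit_lmm,
    lrt,
    variance_explained,
    wald_test,
    _profiled_loglik,
    _profiled_quantities,
)


def _group_design(n, g):
    Z = np.zeros((n, g))
    Z[np.arange(n), np.arange(n) % g] = 1.0
    return Z


def _random_spec(rng, n=50, with_it=True, with_kin=True):
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    blocks = [RandomBlock("grp", _group_design(n, 5), "iid")]
    if with_kin:
        K = 0.4 * np.eye(6) + 0.6
        L = np.linalg.cholesky(K)
        blocks.append(RandomBlock("genotype", _group_design(n, 6),
                                  "kinship_root", root=L))
    if with_it:
        U = 8
        Zi = _group_design(n, U)
        t = rng.normal(size=n)
        Zit = np.concatenate([Zi, Zi * t[:, None]], axis=1)
        blocks.append(RandomBlock("unit", Zit, "intercept_trend", n_units=U))
    y = rng.normal(size=n) + X @ [1.0, 0.3]
    return ModelSpec(y, X, ["intercept", "x"], blocks)


def _theta_to_variances(spec, theta, s2):
    out = {"residual": s2}
    at = 0
    for b in spec.blocks:
        if b.kind == "intercept_trend":
            out[b.label] = (np.exp(theta[at]) * s2, np.exp(theta[at + 1]) * s2,
                            np.tanh(theta[at + 2]))
            at += 3
        else:
            out[b.label] = np.exp(theta[at]) * s2
            at += 1
    return out


def test_intercept_only_closed_form():
    rng = np.random.default_rng(1)
    y = rng.normal(2.0, 1.5, 40)
    spec = ModelSpec(y, np.ones((40, 1)), ["intercept"], [])
    reml = fit_lmm(spec, "reml")
    ml = fit_lmm(spec, "ml")
    ss = ((y - y.mean()) ** 2).sum()
    assert reml.varcomp["residual"] == pytest.approx(ss / 39, rel=1e-12)
    assert ml.varcomp["residual"] == pytest.approx(ss / 40, rel=1e-12)
    # V = I, y = 0 closed-form ML loglik at sigma^2 = 1
    spec0 = ModelSpec(np.zeros(12), np.ones((12, 1)), ["intercept"], [])
    ll = direct_loglik(spec0, {"residual": 1.0}, "ml")
    assert ll == pytest.approx(-(12 / 2) * np.log(2 * np.pi))


def test_balanced_oneway_anova_reml_closed_form():
    rng = np.random.default_rng(2)
    g, m = 8, 6
    n = g * m
    groups = np.repeat(np.arange(g), m)
    Z = np.zeros((n, g))
    Z[np.arange(n), groups] = 1.0
    y = 1.0 + rng.normal(0, np.sqrt(2.0), g)[groups] + rng.normal(0, 1.0, n)
    spec = ModelSpec(y, np.ones((n, 1)), ["intercept"],
                     [RandomBlock("grp", Z, "iid")])
    fit = fit_lmm(spec, "reml")
    gbar = np.array([y[groups == j].mean() for j in range(g)])
    msb = m * ((gbar - y.mean()) ** 2).sum() / (g - 1)
    msw = sum(((y[groups == j] - gbar[j]) ** 2).sum()
              for j in range(g)) / (n - g)
    assert fit.varcomp["residual"] == pytest.approx(msw, abs=1e-6)
    assert fit.varcomp["grp"] == pytest.approx((msb - msw) / m, abs=1e-6)


def test_optimum_matches_direct_loglik():
    rng = np.random.default_rng(3)
    for _ in range(3):
        spec = _random_spec(rng, n=55)
        for method in ("reml", "ml"):
            fit = fit_lmm(spec, method)
            dl = direct_loglik(spec, fit.varcomp, method)
            assert fit.loglik == pytest.approx(dl, abs=1e-6)


def test_objective_equals_direct_at_random_points():
    rng = np.random.default_rng(4)
    spec = _random_spec(rng, n=48)
    d = sum(b.n_params for b in spec.blocks)
    for _ in range(20):
        theta = rng.normal(scale=0.7, size=d)
        for method in ("reml", "ml"):
            pl = _profiled_loglik(spec, theta, method)
            pq = _profiled_quantities(spec, theta)
            dof = spec.n - spec.p if method == "reml" else spec.n
            var = _theta_to_variances(spec, theta, pq["rss"] / dof)
            assert pl == pytest.approx(direct_loglik(spec, var, method),
                                       abs=1e-9)


def test_direct_loglik_guard_and_singular():
    spec = ModelSpec(np.zeros(12), np.ones((12, 1)), ["intercept"], [])
    with pytest.raises(ValueError, match="guarded"):
        direct_loglik(spec, {"residual": 1.0}, "ml", n_guard=10)


def test_reml_translation_invariance():
    rng = np.random.default_rng(5)
    spec = _random_spec(rng, n=40, with_it=False)
    fit = fit_lmm(spec, "reml")
    y2 = spec.y + 7.5 * spec.X[:, 0] - 2.0 * spec.X[:, 1]
    spec2 = ModelSpec(y2, spec.X, spec.x_labels, spec.blocks)
    fit2 = fit_lmm(spec2, "reml")
    assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-6)
    assert fit2.varcomp["residual"] == pytest.approx(
        fit.varcomp["residual"], rel=1e-3)


def test_collinear_columns_pruned_with_names():
    rng = np.random.default_rng(6)
    x = rng.normal(size=30)
    X = np.column_stack([np.ones(30), x, 2 * x])
    spec = ModelSpec(rng.normal(size=30), X, ["intercept", "x", "x2"], [])
    assert len(spec.dropped_columns) == 1
    fit = fit_lmm(spec, "reml")
    with pytest.raises(ValueError, match="collinear"):
        wald_test(fit, spec.dropped_columns[0])


def test_wald_reference_values():
    rng = np.random.default_rng(7)
    n = 200
    x = rng.normal(size=n)
    y = 0.0 * x + rng.normal(size=n)
    spec = ModelSpec(y, np.column_stack([np.ones(n), x]),
                     ["intercept", "x"], [])
    fit = fit_lmm(spec, "reml")
    est, se, t, p = wald_test(fit, "x")
    assert p == pytest.approx(2 * stats.norm.sf(abs(est / se)))
    _, _, _, pt = wald_test(fit, "x", reference="t")
    assert pt == pytest.approx(2 * stats.t.sf(abs(t), n - 2))
    with pytest.raises(ValueError, match="no coefficient"):
        wald_test(fit, "nope")


def test_lrt_basics_and_method_enforcement():
    rng = np.random.default_rng(8)
    n = 60
    x = rng.normal(size=n)
    y = 0.5 * x + rng.normal(size=n)
    X_full = np.column_stack([np.ones(n), x])
    spec_full = ModelSpec(y, X_full, ["intercept", "x"], [])
    spec_red = ModelSpec(y, X_full[:, :1], ["intercept"], [])
    full_ml, red_ml = fit_lmm(spec_full, "ml"), fit_lmm(spec_red, "ml")
    stat, df, p = lrt(full_ml, red_ml)
    assert df == 1 and stat >= 0
    assert p == pytest.approx(stats.chi2.sf(stat, 1))
    # identical models: statistic 0, P = 1 (floored)
    stat0, _, p0 = lrt(full_ml, full_ml, df=1)
    assert stat0 == 0.0 and p0 == 1.0
    # chi-square reference sanity
    assert stats.chi2.sf(3.8415, 1) == pytest.approx(0.05, abs=1e-4)
    with pytest.raises(ValueError, match="same method"):
        lrt(full_ml, fit_lmm(spec_red, "reml"))
    with pytest.raises(ValueError, match="REML"):
        lrt(fit_lmm(spec_full, "reml"), fit_lmm(spec_red, "reml"))


def test_variance_explained_arithmetic_and_truncation():
    rng = np.random.default_rng(9)
    n, g = 60, 12
    Z = _group_design(n, g)
    y = Z @ rng.normal(0, 1.0, g) + rng.normal(size=n)
    spec = ModelSpec(y, np.ones((n, 1)), ["intercept"],
                     [RandomBlock("genotype", Z, "iid")])
    fit_a = fit_lmm(spec, "reml")
    fit_b = fit_lmm(spec, "reml")
    fit_a.varcomp["genotype"], fit_b.varcomp["genotype"] = 2.0, 1.0
    assert variance_explained(fit_a, fit_b) == pytest.approx(50.0)
    # negative difference truncated to zero
    fit_a.varcomp["genotype"], fit_b.varcomp["genotype"] = 1.0, 1.2
    assert variance_explained(fit_a, fit_b) == 0.0
    # zero reduced genetic variance defined as 0
    fit_a.varcomp["genotype"] = 0.0
    assert variance_explained(fit_a, fit_b) == 0.0
    # mismatched responses rejected
    spec2 = ModelSpec(y + 1.0, np.ones((n, 1)), ["intercept"],
                      [RandomBlock("genotype", Z, "iid")])
    with pytest.raises(ValueError, match="mismatched"):
        variance_explained(fit_a, fit_lmm(spec2, "reml"))


def test_boundary_variance_reported_as_zero():
    rng = np.random.default_rng(10)
    n, g = 80, 8
    Z = _group_design(n, g)
    y = rng.normal(size=n)  # no group signal at all
    spec = ModelSpec(y, np.ones((n, 1)), ["intercept"],
                     [RandomBlock("grp", Z, "iid")])
    fit = fit_lmm(spec, "reml")
    if fit.boundary["grp"]:
        assert fit.varcomp["grp"] == 0.0
    else:
        assert fit.varcomp["grp"] >= 0.0


def test_ml_lrt_invariant_to_nested_reparameterization():
    rng = np.random.default_rng(11)
    n = 70
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    y = 0.4 * a + rng.normal(size=n)
    X1 = np.column_stack([np.ones(n), a, b])
    X2 = np.column_stack([np.ones(n), a + b, a - b])  # same span
    red = fit_lmm(ModelSpec(y, np.ones((n, 1)), ["intercept"], []), "ml")
    f1 = fit_lmm(ModelSpec(y, X1, ["i", "a", "b"], []), "ml")
    f2 = fit_lmm(ModelSpec(y, X2, ["i", "u", "v"], []), "ml")
    s1, _, _ = lrt(f1, red, df=2)
    s2, _, _ = lrt(f2, red, df=2)
    assert s1 == pytest.approx(s2, abs=1e-8)
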