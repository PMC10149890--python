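"""ML estimation engine: moments, model builders, discrepancy minimization
and fit indices."""

import numpy as np
import pytest

from facetforge.cfa import (ModelSpec, MomentSet, baseline_chi_square,
                            build_selection_model, build_study1_model,
                            fit_indices, fit_ml, sample_moments,
                            _fml_grad_generic, default_start)
from facetforge.item_model import DataError, PoolError, ResponseMatrix


def two_factor_model(p=6):
    pattern = np.zeros((p, 2), bool)
    pattern[: p // 2, 0] = True
    pattern[p // 2:, 1] = True
    return ModelSpec([f"v{i}" for i in range(p)], ["f1", "f2"], pattern)


def population_sigma(lam=0.7, phi=0.3, p=6):
    L = np.zeros((p, 2))
    L[: p // 2, 0] = lam
    L[p // 2:, 1] = lam
    Phi = np.array([[1.0, phi], [phi, 1.0]])
    return L @ Phi @ L.T + np.diag((1 - lam**2) * np.ones(p))


# ---------------------------------------------------------------------------
# moments


def test_sample_moments_unit_diagonal_and_duplicates():
    rng = np.random.default_rng(0)
    x = rng.integers(1, 6, size=(50, 1))
    values = np.column_stack([x, x, rng.integers(1, 6, size=(50, 1))])
    rm = ResponseMatrix(values, [f"p{i}" for i in range(50)], ["a", "b", "c"])
    mom = sample_moments(rm)
    assert np.allclose(np.diag(mom.S), 1.0)
    assert mom.S[0, 1] == pytest.approx(1.0)


def test_sample_moments_independence_bound():
    rng = np.random.default_rng(1)
    values = rng.integers(1, 6, size=(10_000, 5))
    rm = ResponseMatrix(values, [f"p{i}" for i in range(10_000)],
                        [f"i{j}" for j in range(5)])
    S = sample_moments(rm).S
    off = S[np.triu_indices(5, 1)]
    assert np.abs(off).max() < 0.05


def test_sample_moments_errors():
    values = np.column_stack([np.full(20, 3), np.tile([1, 5], 10)])
    rm = ResponseMatrix(values, [f"p{i}" for i in range(20)], ["c", "v"])
    with pytest.raises(DataError, match="zero-variance"):
        sample_moments(rm)
    small = ResponseMatrix(np.array([[1, 2], [3, 4]]), ["a", "b"], ["x", "y"])
    with pytest.raises(DataError, match="more persons"):
        sample_moments(small)


# ---------------------------------------------------------------------------
# model builders


def test_selection_model_structure(pool52, sim1000):
    _, _, truth = sim1000
    model = build_selection_model(truth.planted_items, pool52)
    sums = model.loading_pattern.sum(axis=0)
    assert dict(zip(model.factor_names, sums)) == {
        "agentic": 8, "antagonistic": 16, "neurotic": 6}
    assert len(model.residual_pairs) == 15          # one per facet
    assert model.n_free == 30 + 3 + 30 + 15
    assert model.df() == 30 * 31 // 2 - 78


def test_selection_model_constraint_violation(pool52, sim1000):
    _, _, truth = sim1000
    bad = list(truth.planted_items)[:-1]            # one facet has 1 item
    with pytest.raises(PoolError, match="exactly 2"):
        build_selection_model(bad + [bad[0]], pool52)


def test_toy_selection_model(toy_pool):
    sel = ["fa_1", "fa_2", "fb_1", "fb_2", "fc_1", "fc_2"]
    model = build_selection_model(sel, toy_pool)
    assert model.loading_pattern.shape == (6, 3)
    assert len(model.residual_pairs) == 3


def test_study1_builders(full_pool):
    m1 = build_study1_model(full_pool, "facets", "item_indicators")
    assert m1.k == 15
    assert m1.n_free == 60 + 105 + 60               # loadings + corrs + resid
    m2 = build_study1_model(full_pool, "two_factor", "facet_indicators")
    assert m2.p == 15 and m2.k == 2
    m7 = build_study1_model(full_pool, "three_factor", "hierarchical")
    assert m7.is_second_order
    assert m7.second_order_pattern.shape == (15, 3)
    # df bookkeeping: p(p+1)/2 - (60 lambda + 15 gamma + 3 phi + 60 theta)
    assert m7.df() == 60 * 61 // 2 - (60 + 15 + 3 + 60)


# ---------------------------------------------------------------------------
# fitting


def test_fit_recovers_population_parameters():
    """At the population matrix the discrepancy minimum is (numerically)
    zero and the generating parameters are recovered."""
    model = two_factor_model()
    mom = MomentSet(population_sigma(), 500)
    fit = fit_ml(model, mom)
    assert fit.converged and fit.admissible
    assert fit.F_min <= 1e-8
    assert np.abs(fit.lambda_hat[model.loading_pattern] - 0.7).max() < 1e-4
    assert abs(fit.phi_hat[0, 1] - 0.3) < 1e-4
    assert np.abs(np.diag(fit.theta_hat) - 0.51).max() < 1e-4


def test_saturated_model_zero_discrepancy():
    """A just-identified (df = 0) one-factor model on its own implied matrix
    reproduces S exactly."""
    lam = np.array([0.8, 0.7, 0.6])
    S = np.outer(lam, lam) + np.diag(1 - lam**2)
    pattern = np.ones((3, 1), bool)
    model = ModelSpec(["a", "b", "c"], ["f"], pattern)
    assert model.df() == 0
    fit = fit_ml(model, MomentSet(S, 100))
    assert fit.F_min <= 1e-10
    idx = fit_indices(fit, MomentSet(S, 100), model)
    assert idx.rmsea == 0.0 and idx.cfi == 1.0 and idx.srmr < 1e-6


def test_oracle_equivalence_generic_minimizer():
    """F_min agrees with an independently coded discrepancy minimized by a
    general-purpose optimizer (no analytic gradient, separate Sigma code)."""
    from scipy.optimize import minimize

    model = two_factor_model()
    rng = np.random.default_rng(42)
    X = rng.multivariate_normal(np.zeros(6), population_sigma(), size=400)
    S = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(S, 1.0)
    mom = MomentSet(S, 400)
    fit = fit_ml(model, mom)
    logdetS = np.linalg.slogdet(S)[1]

    def F_indep(theta):
        L = np.zeros((6, 2))
        L[:3, 0] = theta[:3]
        L[3:, 1] = theta[3:6]
        Phi = np.array([[1.0, theta[6]], [theta[6], 1.0]])
        Sig = L @ Phi @ L.T + np.diag(theta[7:])
        sign, ld = np.linalg.slogdet(Sig)
        if sign <= 0:
            return 1e6
        return ld + np.trace(S @ np.linalg.inv(Sig)) - logdetS - 6

    x0 = np.concatenate([np.full(6, 0.5), [0.2], np.full(6, 0.75)])
    res = minimize(F_indep, x0, method="BFGS",
                   options={"maxiter": 2000, "gtol": 1e-10})
    assert abs(res.fun - fit.F_min) < 1e-6


def test_fast_and_generic_paths_agree(pool52, ctx1000, sim1000):
    """The numba kernel and the generic numpy objective are the same
    function of the parameters."""
    _, _, truth = sim1000
    model = build_selection_model(truth.planted_items, pool52)
    sub = ctx1000.moments.subset(ctx1000.index_of(truth.planted_items))
    x = default_start(model) + 0.01
    from facetforge.cfa import _fml_grad_simple

    fac_of = np.argmax(model.loading_pattern, axis=1).astype(np.int64)
    pi = np.array([i for i, _ in model.residual_pairs], dtype=np.int64)
    pj = np.array([j for _, j in model.residual_pairs], dtype=np.int64)
    F1, g1 = _fml_grad_simple(x, sub.S, sub.logdet, fac_of, pi, pj, model.k)
    F2, g2 = _fml_grad_generic(model, x, sub.S, sub.logdet)
    assert F1 == pytest.approx(F2, abs=1e-10)
    assert np.abs(g1 - g2).max() < 1e-8


def test_analytic_gradient_matches_finite_differences():
    model = two_factor_model()
    rng = np.random.default_rng(3)
    X = rng.multivariate_normal(np.zeros(6), population_sigma(), size=300)
    S = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(S, 1.0)
    logdetS = np.linalg.slogdet(S)[1]
    x = default_start(model) + rng.normal(0, 0.02, model.n_free)
    F, g = _fml_grad_generic(model, x, S, logdetS)
    eps = 1e-6
    num = np.empty_like(g)
    for i in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        num[i] = (_fml_grad_generic(model, xp, S, logdetS)[0]
                  - _fml_grad_generic(model, xm, S, logdetS)[0]) / (2 * eps)
    assert np.abs(g - num).max() < 1e-5


def test_nested_model_monotonicity(toy_pool, toy_data):
    """Freeing the within-facet residual covariances (a nested extension)
    never increases the minimized discrepancy."""
    resp, _, _ = toy_data
    sel = ["fa_1", "fa_2", "fb_1", "fb_2", "fc_1", "fc_2"]
    mom = sample_moments(resp.subset(sel))
    with_pairs = build_selection_model(sel, toy_pool)
    without = ModelSpec(with_pairs.var_names, with_pairs.factor_names,
                        with_pairs.loading_pattern, [])
    f_small = fit_ml(without, mom)
    f_big = fit_ml(with_pairs, mom)
    assert f_big.F_min <= f_small.F_min + 1e-10


def test_scale_invariance_of_indices(toy_pool, toy_data):
    """Indices computed on the correlation metric do not change under linear
    rescaling of the raw responses (correlations are scale-free)."""
    resp, _, _ = toy_data
    sel = ["fa_1", "fa_2", "fb_1", "fb_2", "fc_1", "fc_2"]
    X = resp.subset(sel).values.astype(float)
    S1 = np.corrcoef(X, rowvar=False)
    S2 = np.corrcoef(X * 7.0 + 3.0, rowvar=False)
    assert np.abs(S1 - S2).max() < 1e-12


def test_heywood_case_flagged_inadmissible():
    """A population with a near-unit loading forced through a misspecified
    structure can push a residual variance negative; the fit must report
    inadmissible rather than repair it silently."""
    # indicator 0 duplicated (r = 0.999) while sharing a factor with weakly
    # related items: the model wants theta_0 < 0
    S = np.array([
        [1.0, 0.999, 0.30, 0.30],
        [0.999, 1.0, 0.30, 0.30],
        [0.30, 0.30, 1.0, 0.20],
        [0.30, 0.30, 0.20, 1.0],
    ])
    pattern = np.ones((4, 1), bool)
    model = ModelSpec(list("abcd"), ["f"], pattern)
    fit = fit_ml(model, MomentSet(S, 200))
    if fit.converged:
        assert (np.diag(fit.theta_hat) < 0).any() == (not fit.admissible)


def test_identification_guard():
    pattern = np.ones((2, 1), bool)
    model = ModelSpec(["a", "b"], ["f"], pattern)      # 4 params, 3 moments
    S = np.array([[1.0, 0.5], [0.5, 1.0]])
    with pytest.raises(PoolError, match="not identified"):
        fit_ml(model, MomentSet(S, 100))


# ---------------------------------------------------------------------------
# fit indices


def test_fit_indices_formulas():
    """RMSEA = sqrt((chi2-df)/(df n)), CFI = 1 - (chi2-df)/(chi2_b-df_b)."""
    model = two_factor_model()
    mom = MomentSet(population_sigma(), 500)
    fit = fit_ml(model, mom)
    # synthetic chi-square arithmetic: chi2=100, df=50, n=500, chi2_b=1000, df_b=66
    rmsea = np.sqrt(max(100 - 50, 0) / (50 * 500))
    cfi = 1 - max(100 - 50, 0) / max(1000 - 66, 100 - 50, 0)
    assert rmsea == pytest.approx(0.0447213, abs=1e-6)
    assert cfi == pytest.approx(1 - 50 / 934, abs=1e-12)
    # perfect fit through the actual code path
    idx = fit_indices(fit, mom, model)
    assert idx.chi_square == pytest.approx(0.0, abs=1e-5)
    assert idx.rmsea == 0.0
    assert idx.cfi == 1.0
    assert idx.srmr < 1e-5


def test_baseline_fits_identity_exactly():
    mom = MomentSet(np.eye(4), 100)
    chi2_b, df_b = baseline_chi_square(mom)
    assert chi2_b == pytest.approx(0.0, abs=1e-12)
    assert df_b == 6
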