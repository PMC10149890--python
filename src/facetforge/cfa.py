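"""Maximum-likelihood covariance-structure (CFA) estimation.

Models are fitted to the sample *correlation* matrix of item scores by
minimizing the ML discrepancy

    F_ML(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

over free loadings, factor correlations and residual (co)variances, with
Sigma = Lambda Phi Lambda' + Theta for first-order models and
Sigma = Lambda Omega Lambda' + Theta, Omega = Gamma Phi Gamma' + Psi for
factor->facet->item hierarchies.  Identification is by unit factor
variances (all loadings free); in hierarchical models the first-order
facets are also standardized, with the disturbance variances derived as
Psi_ii = 1 - (Gamma Phi Gamma')_ii.

Residual variances are estimated on the raw (untransformed) scale so that
Heywood cases (negative residual variances) remain detectable; fits with a
negative residual variance or an out-of-bounds correlation are flagged
inadmissible rather than silently repaired.

The hot path (simple-structure first-order models, as evaluated thousands
of times inside the ant-colony search) uses a numba-compiled objective and
analytic gradient; arbitrary patterns and hierarchical models go through an
equivalent pure-numpy route.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.optimize import minimize

from .item_model import ItemPool, ResponseMatrix, PoolError, DataError

GRAD_TOL = 1e-6
_PD_EPS = 1e-12


# ---------------------------------------------------------------------------
# domain types


@dataclass
class MomentSet:
    """Sample correlation matrix S with its sample size."""

    S: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        p = self.S.shape[0]
        if self.S.shape != (p, p):
            raise DataError("S must be square")
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise DataError("S must be symmetric")
        if not np.allclose(np.diag(self.S), 1.0, atol=1e-10):
            raise DataError("S must have unit diagonal (correlation metric)")
        w = np.linalg.eigvalsh(self.S)
        if w.min() < -1e-8:
            raise DataError("S is not positive semi-definite")
        if self.n <= p:
            raise DataError(f"sample size n={self.n} must exceed p={p}")

    @property
    def p(self) -> int:
        return self.S.shape[0]

    @property
    def logdet(self) -> float:
        sign, ld = np.linalg.slogdet(self.S)
        if sign <= 0:
            # singular within tolerance: use pseudo-logdet of positive part
            w = np.linalg.eigvalsh(self.S)
            ld = float(np.sum(np.log(np.clip(w, 1e-12, None))))
        return float(ld)

    def subset(self, idx: Sequence[int]) -> "MomentSet":
        idx = list(idx)
        return MomentSet(self.S[np.ix_(idx, idx)], self.n)


@dataclass
class ModelSpec:
    """Pattern matrices for a first- or second-order factor model."""

    var_names: list[str]
    factor_names: list[str]
    loading_pattern: np.ndarray                 # (p, k) bool, free loadings
    residual_pairs: list[tuple[int, int]] = field(default_factory=list)
    second_order_names: list[str] | None = None
    second_order_pattern: np.ndarray | None = None  # (k, g) bool

    def __post_init__(self) -> None:
        self.loading_pattern = np.asarray(self.loading_pattern, dtype=bool)
        p, k = self.loading_pattern.shape
        if p != len(self.var_names) or k != len(self.factor_names):
            raise PoolError("loading pattern shape does not match names")
        if (self.loading_pattern.sum(axis=1) < 1).any():
            bad = [self.var_names[i] for i in
                   np.flatnonzero(self.loading_pattern.sum(axis=1) < 1)]
            raise PoolError(f"indicator(s) with no loading: {bad}")
        for i, j in self.residual_pairs:
            if i == j:
                raise PoolError("residual pair must join two distinct indicators")
        if self.second_order_pattern is not None:
            self.second_order_pattern = np.asarray(self.second_order_pattern, bool)
            g = self.second_order_pattern.shape[1]
            if self.second_order_names is None or len(self.second_order_names) != g:
                raise PoolError("second-order names do not match pattern")

    # -- parameter bookkeeping ------------------------------------------------

    @property
    def p(self) -> int:
        return len(self.var_names)

    @property
    def k(self) -> int:
        return len(self.factor_names)

    @property
    def is_second_order(self) -> bool:
        return self.second_order_pattern is not None

    @property
    def n_top_factors(self) -> int:
        return (len(self.second_order_names) if self.is_second_order else self.k)

    @property
    def n_free(self) -> int:
        n = int(self.loading_pattern.sum())
        if self.is_second_order:
            n += int(self.second_order_pattern.sum())
        g = self.n_top_factors
        n += g * (g - 1) // 2
        n += self.p                    # residual variances
        n += len(self.residual_pairs)  # residual covariances
        return n

    def df(self) -> int:
        return self.p * (self.p + 1) // 2 - self.n_free

    @property
    def simple_structure(self) -> bool:
        return (not self.is_second_order
                and bool((self.loading_pattern.sum(axis=1) == 1).all()))

    def to_dict(self) -> dict:
        """Sparse-triplet serialization for audit output."""
        out = {
            "var_names": self.var_names,
            "factor_names": self.factor_names,
            "free_loadings": [
                [self.var_names[i], self.factor_names[j]]
                for i, j in zip(*np.nonzero(self.loading_pattern))
            ],
            "residual_pairs": [
                [self.var_names[i], self.var_names[j]] for i, j in self.residual_pairs
            ],
            "df": self.df(),
        }
        if self.is_second_order:
            out["second_order_names"] = self.second_order_names
            out["free_second_order_loadings"] = [
                [self.factor_names[i], self.second_order_names[j]]
                for i, j in zip(*np.nonzero(self.second_order_pattern))
            ]
        return out


@dataclass
class FitResult:
    model: ModelSpec
    lambda_hat: np.ndarray          # (p, k)
    phi_hat: np.ndarray             # top-level factor correlations
    theta_hat: np.ndarray           # (p, p) residual covariance
    gamma_hat: np.ndarray | None    # (k, g) for hierarchical models
    psi_hat: np.ndarray | None      # first-order disturbance variances
    F_min: float
    converged: bool
    admissible: bool
    n_iterations: int
    grad_norm: float

    def implied_sigma(self) -> np.ndarray:
        if self.model.is_second_order:
            P = self.gamma_hat @ self.phi_hat @ self.gamma_hat.T
            Omega = P - np.diag(np.diag(P)) + np.eye(self.model.k)
            return self.lambda_hat @ Omega @ self.lambda_hat.T + self.theta_hat
        return self.lambda_hat @ self.phi_hat @ self.lambda_hat.T + self.theta_hat


@dataclass
class FitIndices:
    chi_square: float
    df: int
    rmsea: float
    cfi: float
    srmr: float
    chi_square_baseline: float
    df_baseline: int

    def to_dict(self) -> dict:
        return {
            "chi_square": self.chi_square,
            "df": self.df,
            "rmsea": self.rmsea,
            "cfi": self.cfi,
            "srmr": self.srmr,
            "chi_square_baseline": self.chi_square_baseline,
            "df_baseline": self.df_baseline,
        }


# ---------------------------------------------------------------------------
# moments


def sample_moments(responses: ResponseMatrix) -> MomentSet:
    """Pearson correlation matrix of the item columns."""
    X = responses.values.astype(float)
    n, p = X.shape
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = [responses.item_ids[j] for j in np.flatnonzero(sd == 0)]
        raise DataError(f"zero-variance item column(s): {bad}")
    if n <= p:
        raise DataError(f"need more persons ({n}) than items ({p})")
    S = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(S, 1.0)
    return MomentSet(S, n)


# ---------------------------------------------------------------------------
# model builders


def build_selection_model(
    selection: Sequence[str], pool: ItemPool, items_per_facet: int = 2
) -> ModelSpec:
    """Three-correlated-factor model for a constrained item subset.

    Each selected item loads on the factor of its facet; every within-facet
    item pair gets a free residual covariance, absorbing the facet-specific
    shared variance (equivalent to nested orthogonal facet factors).
    """
    counts: dict[str, list[str]] = {f: [] for f in pool.facets}
    for iid in selection:
        counts[pool.item(iid).facet].append(iid)
    bad = {f: len(v) for f, v in counts.items() if len(v) != items_per_facet}
    if bad:
        raise PoolError(
            f"selection must have exactly {items_per_facet} items per facet; "
            f"violations: {bad}"
        )
    fmap = pool.map_three
    factors = list(fmap.factors)
    var_names = list(selection)
    p, k = len(var_names), len(factors)
    pattern = np.zeros((p, k), dtype=bool)
    for i, iid in enumerate(var_names):
        pattern[i, factors.index(fmap.assignment[pool.item(iid).facet])] = True
    pairs: list[tuple[int, int]] = []
    for facet in pool.facets:
        idx = [var_names.index(i) for i in counts[facet]]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                pairs.append((idx[a], idx[b]))
    return ModelSpec(var_names, factors, pattern, pairs)


def build_study1_model(
    pool: ItemPool, level: str, granularity: str
) -> ModelSpec:
    """Pattern builders for the confirmatory structure battery.

    level: 'facets' | 'two_factor' | 'three_factor'
    granularity: 'facet_indicators' | 'item_indicators' | 'hierarchical'
    """
    if level == "facets":
        if granularity != "item_indicators":
            raise PoolError("the correlated-facets model requires item indicators")
        var_names = list(pool.item_ids)
        factors = list(pool.facets)
        pattern = np.zeros((len(var_names), len(factors)), dtype=bool)
        for i, iid in enumerate(var_names):
            pattern[i, factors.index(pool.item(iid).facet)] = True
        return ModelSpec(var_names, factors, pattern)

    fmap = pool.factor_map("three" if level == "three_factor" else "two")
    factors = list(fmap.factors)
    if granularity == "facet_indicators":
        var_names = list(pool.facets)
        pattern = np.zeros((len(var_names), len(factors)), dtype=bool)
        for i, facet in enumerate(var_names):
            pattern[i, factors.index(fmap.assignment[facet])] = True
        return ModelSpec(var_names, factors, pattern)
    if granularity == "item_indicators":
        var_names = list(pool.item_ids)
        pattern = np.zeros((len(var_names), len(factors)), dtype=bool)
        for i, iid in enumerate(var_names):
            facet = pool.item(iid).facet
            pattern[i, factors.index(fmap.assignment[facet])] = True
        return ModelSpec(var_names, factors, pattern)
    if granularity == "hierarchical":
        for facet in pool.facets:
            if len(pool.items_of_facet(facet)) < 2:
                raise PoolError(
                    f"facet {facet!r} has < 2 indicators; hierarchical model "
                    "is not identified"
                )
        var_names = list(pool.item_ids)
        facet_names = list(pool.facets)
        pattern = np.zeros((len(var_names), len(facet_names)), dtype=bool)
        for i, iid in enumerate(var_names):
            pattern[i, facet_names.index(pool.item(iid).facet)] = True
        second = np.zeros((len(facet_names), len(factors)), dtype=bool)
        for i, facet in enumerate(facet_names):
            second[i, factors.index(fmap.assignment[facet])] = True
        return ModelSpec(
            var_names, facet_names, pattern,
            second_order_names=factors, second_order_pattern=second,
        )
    raise PoolError(f"unknown granularity {granularity!r}")


# ---------------------------------------------------------------------------
# fast objective: simple-structure first-order models


@njit(cache=True)
def _fml_grad_simple(params, S, logdetS, fac_of, pair_i, pair_j, k):  # pragma: no cover
    p = S.shape[0]
    m = pair_i.size
    nphi = k * (k - 1) // 2
    lam = params[:p]
    phiv = params[p:p + nphi]
    theta = params[p + nphi:2 * p + nphi]
    thp = params[2 * p + nphi:]

    Phi = np.eye(k)
    idx = 0
    for a in range(k):
        for b in range(a + 1, k):
            Phi[a, b] = phiv[idx]
            Phi[b, a] = phiv[idx]
            idx += 1

    Sigma = np.empty((p, p))
    for i in range(p):
        fi = fac_of[i]
        for j in range(p):
            Sigma[i, j] = lam[i] * lam[j] * Phi[fi, fac_of[j]]
    for i in range(p):
        Sigma[i, i] += theta[i]
    for t in range(m):
        Sigma[pair_i[t], pair_j[t]] += thp[t]
        Sigma[pair_j[t], pair_i[t]] += thp[t]

    # manual Cholesky with positive-definiteness check
    L = np.zeros((p, p))
    ok = True
    for i in range(p):
        if not ok:
            break
        for j in range(i + 1):
            s = Sigma[i, j]
            for t in range(j):
                s -= L[i, t] * L[j, t]
            if i == j:
                if s <= _PD_EPS:
                    ok = False
                    break
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]

    if ok:
        logdet = 0.0
        for i in range(p):
            logdet += 2.0 * np.log(L[i, i])
        # invert L (forward substitution), then Sigma^-1 = Linv' Linv
        Linv = np.zeros((p, p))
        for i in range(p):
            Linv[i, i] = 1.0 / L[i, i]
            for j in range(i):
                s = 0.0
                for t in range(j, i):
                    s -= L[i, t] * Linv[t, j]
                Linv[i, j] = s / L[i, i]
        Siginv = Linv.T @ Linv
        F = logdet - logdetS - p
        for i in range(p):
            for j in range(p):
                F += S[i, j] * Siginv[i, j]
        A = Siginv - Siginv @ S @ Siginv
        scale = 1.0
    else:
        # penalty branch: push the smallest eigenvalue of Sigma upward
        w, V = np.linalg.eigh(Sigma)
        v = V[:, 0]
        A = np.empty((p, p))
        for i in range(p):
            for j in range(p):
                A[i, j] = -v[i] * v[j]
        F = 1.0e4 * (1.0 - w[0])
        scale = 1.0e4

    # gradient projection: dF = tr(A dSigma)
    Lam = np.zeros((p, k))
    for i in range(p):
        Lam[i, fac_of[i]] = lam[i]
    G = (A @ Lam) @ Phi            # p x k
    M = Lam.T @ A @ Lam            # k x k
    grad = np.empty(params.size)
    for i in range(p):
        grad[i] = 2.0 * scale * G[i, fac_of[i]]
    idx = 0
    for a in range(k):
        for b in range(a + 1, k):
            grad[p + idx] = 2.0 * scale * M[a, b]
            idx += 1
    for i in range(p):
        grad[p + nphi + i] = scale * A[i, i]
    for t in range(m):
        grad[2 * p + nphi + t] = 2.0 * scale * A[pair_i[t], pair_j[t]]
    return F, grad


# ---------------------------------------------------------------------------
# generic objective (arbitrary patterns, hierarchical models)


def _unpack(model: ModelSpec, params: np.ndarray):
    p, k = model.p, model.k
    lr, lc = np.nonzero(model.loading_pattern)
    pos = 0
    Lam = np.zeros((p, k))
    Lam[lr, lc] = params[pos:pos + lr.size]
    pos += lr.size
    Gam = None
    if model.is_second_order:
        gr, gc = np.nonzero(model.second_order_pattern)
        g = len(model.second_order_names)
        Gam = np.zeros((k, g))
        Gam[gr, gc] = params[pos:pos + gr.size]
        pos += gr.size
    g = model.n_top_factors
    nphi = g * (g - 1) // 2
    Phi = np.eye(g)
    iu = np.triu_indices(g, 1)
    Phi[iu] = params[pos:pos + nphi]
    Phi[(iu[1], iu[0])] = params[pos:pos + nphi]
    pos += nphi
    theta = params[pos:pos + p]
    pos += p
    thp = params[pos:]
    return Lam, Gam, Phi, theta, thp


def _sigma_of(model: ModelSpec, params: np.ndarray) -> np.ndarray:
    Lam, Gam, Phi, theta, thp = _unpack(model, params)
    if model.is_second_order:
        P = Gam @ Phi @ Gam.T
        Omega = P - np.diag(np.diag(P)) + np.eye(model.k)
        Sigma = Lam @ Omega @ Lam.T
    else:
        Sigma = Lam @ Phi @ Lam.T
    Sigma = Sigma + np.diag(theta)
    for t, (i, j) in enumerate(model.residual_pairs):
        Sigma[i, j] += thp[t]
        Sigma[j, i] += thp[t]
    return Sigma


def _fml_grad_generic(model: ModelSpec, params, S, logdetS):
    p = model.p
    Lam, Gam, Phi, theta, thp = _unpack(model, params)
    Sigma = _sigma_of(model, params)
    w_min = None
    try:
        c = np.linalg.cholesky(Sigma)
        ok = True
    except np.linalg.LinAlgError:
        ok = False
    if ok:
        Siginv = np.linalg.inv(Sigma)
        sign, logdet = np.linalg.slogdet(Sigma)
        F = logdet + float(np.sum(S * Siginv)) - logdetS - p
        A = Siginv - Siginv @ S @ Siginv
        scale = 1.0
    else:
        w, V = np.linalg.eigh(Sigma)
        v = V[:, 0]
        A = -np.outer(v, v)
        F = 1.0e4 * (1.0 - w[0])
        scale = 1.0e4

    grads = []
    if model.is_second_order:
        Omega = Gam @ Phi @ Gam.T
        Omega = Omega - np.diag(np.diag(Omega)) + np.eye(model.k)
        G = 2.0 * scale * (A @ Lam) @ Omega
        lr, lc = np.nonzero(model.loading_pattern)
        grads.append(G[lr, lc])
        B = Lam.T @ A @ Lam
        B0 = B - np.diag(np.diag(B))
        Gg = 2.0 * scale * (B0 @ Gam) @ Phi
        gr, gc = np.nonzero(model.second_order_pattern)
        grads.append(Gg[gr, gc])
        Mp = Gam.T @ B0 @ Gam
        iu = np.triu_indices(model.n_top_factors, 1)
        grads.append(2.0 * scale * Mp[iu])
    else:
        G = 2.0 * scale * (A @ Lam) @ Phi
        lr, lc = np.nonzero(model.loading_pattern)
        grads.append(G[lr, lc])
        M = Lam.T @ A @ Lam
        iu = np.triu_indices(model.k, 1)
        grads.append(2.0 * scale * M[iu])
    grads.append(scale * np.diag(A))
    pair_grads = np.array(
        [2.0 * scale * A[i, j] for i, j in model.residual_pairs], dtype=float
    )
    grads.append(pair_grads)
    return F, np.concatenate(grads)


# ---------------------------------------------------------------------------
# fitting


def default_start(model: ModelSpec) -> np.ndarray:
    """Deterministic start values: loadings 0.5, factor correlations 0.2,
    residual variances 0.75, residual covariances 0.05."""
    parts = [np.full(int(model.loading_pattern.sum()), 0.5)]
    if model.is_second_order:
        parts.append(np.full(int(model.second_order_pattern.sum()), 0.5))
    g = model.n_top_factors
    parts.append(np.full(g * (g - 1) // 2, 0.2))
    parts.append(np.full(model.p, 0.75))
    parts.append(np.full(len(model.residual_pairs), 0.05))
    return np.concatenate(parts)


def fit_ml(
    model: ModelSpec,
    moments: MomentSet,
    start: np.ndarray | None = None,
    max_iter: int = 500,
    grad_tol: float = GRAD_TOL,
) -> FitResult:
    """Minimize the ML discrepancy; deterministic given start values.

    Non-convergence is reported via ``converged=False``, never raised.
    """
    if moments.p != model.p:
        raise DataError(
            f"moment matrix has {moments.p} variables, model expects {model.p}"
        )
    if model.df() < 0:
        raise PoolError(
            f"model not identified: df = {model.df()} < 0 "
            f"({model.n_free} free parameters)"
        )
    S = moments.S
    logdetS = moments.logdet
    x0 = default_start(model) if start is None else np.asarray(start, float)

    if model.simple_structure:
        fac_of = np.argmax(model.loading_pattern, axis=1).astype(np.int64)
        pair_i = np.array([i for i, _ in model.residual_pairs], dtype=np.int64)
        pair_j = np.array([j for _, j in model.residual_pairs], dtype=np.int64)
        k = model.k

        def fun(x):
            return _fml_grad_simple(x, S, logdetS, fac_of, pair_i, pair_j, k)
    else:

        def fun(x):
            return _fml_grad_generic(model, x, S, logdetS)

    res = minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "maxfun": 10 * max_iter,
                 "ftol": 1e-14, "gtol": 1e-8},
    )
    F, g = fun(res.x)
    grad_norm = float(np.abs(g).max())
    if grad_norm > grad_tol:
        # polish with a fresh BFGS pass from the current point
        res2 = minimize(fun, res.x, jac=True, method="L-BFGS-B",
                        options={"maxiter": max_iter, "maxfun": 10 * max_iter,
                                 "ftol": 1e-16, "gtol": 1e-10})
        F2, g2 = fun(res2.x)
        if F2 <= F:
            res, F, g = res2, F2, g2
            grad_norm = float(np.abs(g).max())
    converged = bool(grad_norm <= grad_tol)

    Lam, Gam, Phi, theta, thp = _unpack(model, res.x)
    Theta = np.diag(theta.copy())
    for t, (i, j) in enumerate(model.residual_pairs):
        Theta[i, j] = thp[t]
        Theta[j, i] = thp[t]
    psi = None
    admissible = converged
    if model.is_second_order:
        P = Gam @ Phi @ Gam.T
        psi = 1.0 - np.diag(P)
        if (psi < -1e-8).any():
            admissible = False
    if (theta < -1e-8).any():
        admissible = False
    g_top = model.n_top_factors
    iu = np.triu_indices(g_top, 1)
    if (np.abs(Phi[iu]) > 1.0 + 1e-8).any():
        admissible = False

    return FitResult(
        model=model, lambda_hat=Lam, phi_hat=Phi, theta_hat=Theta,
        gamma_hat=Gam, psi_hat=psi,
        F_min=float(max(F, 0.0)), converged=converged, admissible=admissible,
        n_iterations=int(res.nit), grad_norm=grad_norm,
    )


# ---------------------------------------------------------------------------
# fit indices


def baseline_chi_square(moments: MomentSet) -> tuple[float, int]:
    """Independence baseline on the correlation metric.

    With unit variances the baseline Sigma is the identity, so
    F_b = -ln|S| in closed form; df_b = p(p-1)/2.
    """
    p = moments.p
    F_b = -moments.logdet
    return moments.n * max(F_b, 0.0), p * (p - 1) // 2


def fit_indices(fit: FitResult, moments: MomentSet, model: ModelSpec | None = None) -> FitIndices:
    """Chi-square (n * F_min), RMSEA, CFI and SRMR.

    df = 0 models fit exactly by construction: RMSEA is defined as 0 and
    CFI as 1 (documented convention).
    """
    model = model or fit.model
    n = moments.n
    chi2 = n * fit.F_min
    df = model.df()
    chi2_b, df_b = baseline_chi_square(moments)
    if df > 0:
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * n)))
    else:
        rmsea = 0.0
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 or df == 0 else 1.0 - max(chi2 - df, 0.0) / denom
    resid = moments.S - fit.implied_sigma()
    iu = np.triu_indices(moments.p, 0)
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
    return FitIndices(
        chi_square=float(chi2), df=int(df), rmsea=rmsea, cfi=float(cfi),
        srmr=srmr, chi_square_baseline=float(chi2_b), df_baseline=int(df_b),
    )
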