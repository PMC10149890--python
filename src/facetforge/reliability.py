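"""Scale scoring, internal consistency, factor saturation and validity.

Scales are scored as per-person means of (possibly reverse-scored) item
ratings, so scores live on the same 1-5 metric as the items.  Reliability
comes in two flavours: Cronbach's alpha from the observed item covariances,
and McDonald's omega (factor saturation) from a fitted standardized factor
model, with the within-facet residual covariances of the selection model
included in the error term by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cfa import FitResult, ModelSpec
from .item_model import CriterionTable, DataError, ResponseMatrix, LIKERT_MAX, LIKERT_MIN


@dataclass
class ScaleScores:
    values: np.ndarray          # persons x scales
    person_ids: list[str]
    scale_ids: list[str]

    def column(self, scale_id: str) -> np.ndarray:
        return self.values[:, self.scale_ids.index(scale_id)]


@dataclass
class ReliabilityValue:
    scale_id: str
    coefficient: float
    kind: str                   # "alpha" | "omega"


@dataclass
class TestResult:
    statistic: float
    df: float                   # Welch-Satterthwaite
    p_value: float
    mean_a: float
    mean_b: float


def score_scales(
    responses: ResponseMatrix,
    memberships: dict[str, list[tuple[str, int]]],
) -> ScaleScores:
    """Per-person mean item rating per scale.

    ``memberships`` maps a scale name to ``(item_id, sign)`` pairs as
    produced by :func:`~facetforge.item_model.scale_memberships`; items with
    sign -1 are reverse-scored (6 - x) before averaging.
    """
    scale_ids = list(memberships)
    out = np.empty((responses.n_persons, len(scale_ids)))
    for s, sid in enumerate(scale_ids):
        members = memberships[sid]
        if not members:
            raise DataError(f"scale {sid!r} has an empty membership list")
        cols = []
        for iid, sign in members:
            x = responses.column(iid).astype(float)
            cols.append(x if sign > 0 else (LIKERT_MAX + LIKERT_MIN) - x)
        out[:, s] = np.mean(cols, axis=0)
    return ScaleScores(out, responses.person_ids, scale_ids)


def alpha_from_cov(cov: np.ndarray) -> float:
    """Cronbach's alpha from an item covariance matrix."""
    cov = np.asarray(cov, float)
    k = cov.shape[0]
    if k < 2:
        raise DataError("alpha requires at least 2 items")
    total_var = float(cov.sum())
    if total_var <= 0:
        raise DataError("zero total variance")
    return (k / (k - 1)) * (1.0 - float(np.trace(cov)) / total_var)


def cronbach_alpha(responses: ResponseMatrix, items: list[str]) -> ReliabilityValue:
    X = np.column_stack([responses.column(i) for i in items]).astype(float)
    if (X.std(axis=0) == 0).any():
        raise DataError("zero-variance item in alpha computation")
    cov = np.cov(X, rowvar=False)
    return ReliabilityValue("+".join(items), alpha_from_cov(cov), "alpha")


def mcdonald_omega(
    fit: FitResult,
    model: ModelSpec | None = None,
    factor: str | int = 0,
    signs: dict[str, int] | None = None,
    include_residual_cov: bool = True,
) -> ReliabilityValue:
    """Factor saturation omega of one factor's indicator composite.

    omega = (sum lambda)^2 / ((sum lambda)^2 + sum theta_ii + 2 sum theta_ij)
    on the standardized metric, over the factor's indicators.  ``signs``
    (item_id -> +-1, from the scoring map) reverse-scores indicators whose
    keyed direction opposes the factor; the residual covariances of
    same-facet pairs are part of the error term unless
    ``include_residual_cov=False``.
    """
    model = model or fit.model
    if not (fit.converged and fit.admissible):
        raise DataError(
            "omega requires a converged, admissible fit; apply the objective's "
            "non-convergence policy instead of computing reliability"
        )
    f = model.factor_names.index(factor) if isinstance(factor, str) else factor
    idx = np.flatnonzero(model.loading_pattern[:, f])
    s = np.ones(idx.size)
    if signs:
        s = np.array([signs.get(model.var_names[i], 1) for i in idx], float)
    lam = fit.lambda_hat[idx, f] * s
    load_sum = float(lam.sum()) ** 2
    err = float(np.trace(fit.theta_hat[np.ix_(idx, idx)]))
    if include_residual_cov:
        T = fit.theta_hat[np.ix_(idx, idx)] * np.outer(s, s)
        err += float(T.sum() - np.trace(T))
    denom = load_sum + err
    name = model.factor_names[f]
    if denom <= 0:
        raise DataError(f"non-positive composite variance for factor {name!r}")
    return ReliabilityValue(name, load_sum / denom, "omega")


def criterion_correlations(
    scores: ScaleScores,
    criteria: CriterionTable,
    mapping: dict[str, list[str]],
) -> dict[tuple[str, str], float]:
    """Pearson r between each factor score and its mapped criterion columns."""
    if scores.person_ids != criteria.person_ids:
        raise DataError("scores and criteria are not person-aligned")
    out: dict[tuple[str, str], float] = {}
    for factor, crit_ids in mapping.items():
        if factor not in scores.scale_ids:
            raise DataError(f"unmapped factor {factor!r} in criterion mapping")
        x = scores.column(factor)
        if x.std() == 0:
            raise DataError(f"zero-variance factor score {factor!r}")
        for cid in crit_ids:
            y = criteria.column(cid)
            if y.std() == 0:
                raise DataError(f"zero-variance criterion {cid!r}")
            out[(factor, cid)] = float(np.corrcoef(x, y)[0, 1])
    return out


def welch_t(scores_a: np.ndarray, scores_b: np.ndarray) -> TestResult:
    """Welch's independent-samples t-test (unequal variances)."""
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.size < 2 or b.size < 2:
        raise DataError("each group needs at least 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb == 0:
        df = float(a.size + b.size - 2)
        t, p = 0.0, 1.0
    else:
        df = (va + vb) ** 2 / (
            va**2 / (a.size - 1) + vb**2 / (b.size - 1)
        )
    return TestResult(float(t), float(df), float(p), float(a.mean()), float(b.mean()))
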