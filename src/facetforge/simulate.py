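"""Synthetic Likert data with planted factor/facet structure.

The generator emulates the statistical structure the selection pipeline
assumes: three correlated content factors (agentic, antagonistic, neurotic),
one orthogonal nuisance factor per facet carrying the facet-specific shared
variance, heterogeneous primary loadings, Gaussian item continua discretized
to a 1-5 Likert scale by fixed thresholds, and external criterion variables
generated from the latent factors at chosen population validities.

Because two items per facet are planted with clearly higher loadings than
the rest, the ground-truth optimal brief form is known, which gives the
search algorithms a recoverable target without any real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .item_model import CriterionTable, ItemPool, ResponseMatrix, DataError

# Three-factor intercorrelations of the brief form in the pooled human data
# (agentic-antagonistic .51, agentic-neurotic .03, antagonistic-neurotic -.04).
DEFAULT_FACTOR_CORR = np.array([
    [1.00, 0.51, 0.03],
    [0.51, 1.00, -0.04],
    [0.03, -0.04, 1.00],
])

DEFAULT_THRESHOLDS = (-1.5, -0.5, 0.5, 1.5)

# Population validity of each external criterion for its latent factor.
DEFAULT_CRITERION_SPEC: dict[str, tuple[str, float]] = {
    "npi_leadership_authority": ("agentic", 0.65),
    "narq_admiration": ("agentic", 0.65),
    "npi_entitlement_exploitativeness": ("antagonistic", 0.55),
    "narq_rivalry": ("antagonistic", 0.55),
    "pes": ("antagonistic", 0.55),
    "hsns": ("neurotic", 0.60),
    "pni_vulnerability": ("neurotic", 0.60),
}

STRONG_LOADING = 0.80
WEAK_LOADING = 0.45
NUISANCE_LOADING = 0.30


@dataclass
class PopulationSpec:
    """Generating parameters with known ground truth."""

    factor_names: list[str]
    factor_corr: np.ndarray                       # 3x3 PSD correlation matrix
    item_ids: list[str]
    item_factor: list[str]                        # per item, content factor
    item_facet: list[str]
    loadings: np.ndarray                          # signed primary loading per item
    nuisance_loadings: np.ndarray                 # facet-factor loading per item
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    criterion_spec: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_CRITERION_SPEC)
    )

    def __post_init__(self) -> None:
        self.factor_corr = np.asarray(self.factor_corr, float)
        self.loadings = np.asarray(self.loadings, float)
        self.nuisance_loadings = np.asarray(self.nuisance_loadings, float)
        if (self.loadings**2 + self.nuisance_loadings**2 >= 1.0).any():
            raise DataError("lambda^2 + gamma^2 must stay below 1 for every item")
        if np.linalg.eigvalsh(self.factor_corr).min() < -1e-10:
            raise DataError("factor correlation matrix is not PSD")
        if list(self.thresholds) != sorted(self.thresholds) or len(
            set(self.thresholds)
        ) != len(self.thresholds):
            raise DataError("thresholds must be strictly increasing")

    @property
    def residual_sd(self) -> np.ndarray:
        return np.sqrt(1.0 - self.loadings**2 - self.nuisance_loadings**2)

    def implied_continuous_corr(self) -> np.ndarray:
        """Model-implied correlation matrix of the pre-discretization items."""
        p = len(self.item_ids)
        fidx = [self.factor_names.index(f) for f in self.item_factor]
        lam = self.loadings
        R = np.empty((p, p))
        for i in range(p):
            for j in range(p):
                R[i, j] = lam[i] * lam[j] * self.factor_corr[fidx[i], fidx[j]]
                if self.item_facet[i] == self.item_facet[j] and i != j:
                    R[i, j] += self.nuisance_loadings[i] * self.nuisance_loadings[j]
        np.fill_diagonal(R, 1.0)
        return R


@dataclass
class GroundTruth:
    planted_best: dict[str, list[str]]            # facet -> items_per_facet ids

    @property
    def planted_items(self) -> list[str]:
        return [i for items in self.planted_best.values() for i in items]


def default_population_spec(
    pool: ItemPool, items_per_facet: int = 2
) -> tuple[PopulationSpec, GroundTruth]:
    """Plant ``items_per_facet`` strong items (|lambda| = 0.80) per facet.

    The strong items are the first candidates of each facet that are neither
    content-redundant nor reverse-keyed, so the planted optimum survives the
    standard pool filters.  Facets scored negatively in the three-factor map
    (indifference under neurotic narcissism) get negative primary loadings,
    mirroring the keyed direction of the real instrument.
    """
    fmap = pool.map_three
    item_ids, item_factor, item_facet = [], [], []
    loadings, nuisance = [], []
    planted: dict[str, list[str]] = {}
    for facet in pool.facets:
        items = pool.items_of_facet(facet)
        clean = [
            it.item_id for it in items
            if not it.content_redundant and not it.reverse_keyed
        ]
        if len(clean) < items_per_facet:
            raise DataError(
                f"facet {facet!r} has too few unflagged items to plant a best set"
            )
        strong = clean[:items_per_facet]
        planted[facet] = strong
        sign = fmap.signs[facet]
        for it in items:
            item_ids.append(it.item_id)
            item_facet.append(facet)
            item_factor.append(fmap.assignment[facet])
            lam = STRONG_LOADING if it.item_id in strong else WEAK_LOADING
            loadings.append(sign * lam)
            nuisance.append(NUISANCE_LOADING)
    spec = PopulationSpec(
        factor_names=list(fmap.factors),
        factor_corr=DEFAULT_FACTOR_CORR.copy(),
        item_ids=item_ids,
        item_factor=item_factor,
        item_facet=item_facet,
        loadings=np.array(loadings),
        nuisance_loadings=np.array(nuisance),
    )
    return spec, GroundTruth(planted_best=planted)


def discretize(latent: np.ndarray, thresholds=DEFAULT_THRESHOLDS) -> np.ndarray:
    """Map a continuous matrix to 1..5 by strictly increasing thresholds."""
    t = np.asarray(thresholds, float)
    if t.size != 4 or (np.diff(t) <= 0).any():
        raise DataError("need 4 strictly increasing thresholds")
    return (np.searchsorted(t, latent, side="left") + 1).astype(np.int64)


def simulate_responses(
    spec: PopulationSpec, n: int, seed: int
) -> tuple[ResponseMatrix, CriterionTable, dict[str, np.ndarray]]:
    """Draw persons from the population and return Likert responses,
    criterion scores, and the latent factor draws.

    Criteria are generated as ``r * factor + sqrt(1 - r^2) * noise`` on unit
    variances, so the target validity ``r`` is the population correlation
    with the *latent* factor (observed scale-score correlations are
    attenuated by unreliability and discretization).
    """
    if n < 1:
        raise DataError("need at least one person")
    rng = np.random.default_rng(seed)
    p = len(spec.item_ids)
    k = len(spec.factor_names)
    facets = list(dict.fromkeys(spec.item_facet))

    L = np.linalg.cholesky(spec.factor_corr + 1e-12 * np.eye(k))
    factors = rng.standard_normal((n, k)) @ L.T
    nuis = rng.standard_normal((n, len(facets)))
    eps = rng.standard_normal((n, p))

    fidx = np.array([spec.factor_names.index(f) for f in spec.item_factor])
    uidx = np.array([facets.index(f) for f in spec.item_facet])
    latent = (
        factors[:, fidx] * spec.loadings
        + nuis[:, uidx] * spec.nuisance_loadings
        + eps * spec.residual_sd
    )
    values = discretize(latent, spec.thresholds)
    person_ids = [f"p{i+1}" for i in range(n)]
    responses = ResponseMatrix(values, person_ids, list(spec.item_ids))

    crit_ids = list(spec.criterion_spec)
    crit = np.empty((n, len(crit_ids)))
    for j, cid in enumerate(crit_ids):
        factor, r = spec.criterion_spec[cid]
        f = factors[:, spec.factor_names.index(factor)]
        crit[:, j] = r * f + np.sqrt(1.0 - r**2) * rng.standard_normal(n)
    criteria = CriterionTable(crit, person_ids, crit_ids)
    latents = {
        name: factors[:, i] for i, name in enumerate(spec.factor_names)
    }
    return responses, criteria, latents
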