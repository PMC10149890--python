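"""Ant-colony item selection with an exhaustive-search oracle.

Each "ant" assembles a feasible brief form by drawing, independently per
facet, a fixed number of distinct items with probability proportional to
their pheromone weight.  Every candidate is scored by fitting the
three-factor selection model and evaluating the composite objective; the
iteration-best candidate deposits pheromone on its items after uniform
evaporation.  A run stops after a configurable number of iterations without
strict improvement of the global best, and several independently seeded
runs are pooled, keeping the overall best solution.

Because the objective depends only on the item subset (deterministic cold
starts), evaluations are memoized per data set; repeated visits to the same
subset are free and bitwise-identical, which also lets the exhaustive
oracle and the stochastic search agree exactly on shared solutions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cfa import (FitIndices, MomentSet, build_selection_model, fit_indices,
                  fit_ml, sample_moments)
from .item_model import (CriterionTable, ItemPool, PoolError, ResponseMatrix,
                         scale_memberships)
from .objective import ObjectiveConfig, ObjectiveValue, composite_objective
from .reliability import ReliabilityValue, mcdonald_omega

logger = logging.getLogger(__name__)

PHEROMONE_FLOOR = 1e-6


@dataclass
class ACOConfig:
    n_ants: int = 50
    stop_stagnation: int = 30
    max_iterations: int = 500
    evaporation: float = 0.10
    n_runs: int = 10
    base_seed: int = 0
    seeds: list[int] | None = None
    items_per_facet: int = 2

    def __post_init__(self) -> None:
        if self.n_ants < 1 or self.n_runs < 1:
            raise ValueError("n_ants and n_runs must be >= 1")
        if not 0.0 <= self.evaporation < 1.0:
            raise ValueError("evaporation must lie in [0, 1)")
        if self.seeds is not None and len(self.seeds) != self.n_runs:
            raise ValueError("seeds list must have one entry per run")

    def run_seeds(self) -> list:
        if self.seeds is not None:
            return list(self.seeds)
        ss = np.random.SeedSequence(self.base_seed)
        return list(ss.spawn(self.n_runs))

    def to_dict(self) -> dict:
        return {
            "n_ants": self.n_ants,
            "stop_stagnation": self.stop_stagnation,
            "max_iterations": self.max_iterations,
            "evaporation": self.evaporation,
            "n_runs": self.n_runs,
            "base_seed": self.base_seed,
            "seeds": self.seeds,
            "items_per_facet": self.items_per_facet,
        }


@dataclass
class EvaluatedSolution:
    selection: tuple[str, ...]
    objective: ObjectiveValue
    indices: FitIndices | None
    omegas: list[ReliabilityValue] | None
    correlations: dict[tuple[str, str], float] | None
    seed: object = None
    iteration: int | None = None

    @property
    def composite(self) -> float:
        return self.objective.composite

    def snapshot(self) -> dict:
        return {
            "selection": list(self.selection),
            "objective": self.objective.to_dict(),
            "fit_indices": self.indices.to_dict() if self.indices else None,
            "omega": {o.scale_id: o.coefficient for o in self.omegas}
            if self.omegas else None,
            "criterion_correlations": {
                f"{f}:{c}": r for (f, c), r in self.correlations.items()
            } if self.correlations else None,
        }


@dataclass
class PheromoneState:
    pool: ItemPool
    pheromone: dict[str, float]
    items_per_facet: int
    iteration: int = 0
    global_best: EvaluatedSolution | None = None


@dataclass
class ValidationReport:
    selection: tuple[str, ...]
    selection_sample: EvaluatedSolution
    validation_sample: EvaluatedSolution
    degraded: bool
    degradation_margin: float

    def to_dict(self) -> dict:
        return {
            "selection": list(self.selection),
            "selection_sample": self.selection_sample.snapshot(),
            "validation_sample": self.validation_sample.snapshot(),
            "degraded": self.degraded,
            "degradation_margin": self.degradation_margin,
        }


@dataclass
class ACOResult:
    best: EvaluatedSolution
    run_bests: list[EvaluatedSolution]
    trace: list[dict]
    n_evaluations: int
    n_distinct_evaluations: int


# ---------------------------------------------------------------------------
# evaluation context: everything the objective needs, precomputed once


class EvaluationContext:
    """Precomputed moments and covariances for fast candidate scoring.

    The correlation submatrix of any selection is a view into the full item
    correlation matrix, and scale-score/criterion correlations follow from
    item-level covariances, so evaluation cost is independent of the number
    of persons.
    """

    def __init__(
        self,
        pool: ItemPool,
        responses: ResponseMatrix,
        criteria: CriterionTable,
    ) -> None:
        criteria.check_alignment(responses)
        self.pool = pool
        self.item_ids = list(responses.item_ids)
        self.moments = sample_moments(responses)
        X = responses.values.astype(float)
        C = criteria.values
        self.item_cov = np.cov(X, rowvar=False)
        Xc = X - X.mean(axis=0)
        Cc = C - C.mean(axis=0)
        n = X.shape[0]
        self.item_crit_cov = Xc.T @ Cc / (n - 1)
        self.crit_var = C.var(axis=0, ddof=1)
        self.criterion_ids = list(criteria.criterion_ids)
        fmap = pool.map_three
        self.item_sign = {
            iid: fmap.signs[pool.item(iid).facet] for iid in self.item_ids
        }
        self.item_factor = {
            iid: fmap.assignment[pool.item(iid).facet] for iid in self.item_ids
        }

    def index_of(self, item_ids: Sequence[str]) -> list[int]:
        return [self.item_ids.index(i) for i in item_ids]

    def score_criterion_corr(
        self, selection: Sequence[str], mapping: dict[str, list[str]]
    ) -> dict[tuple[str, str], float]:
        """Pearson r between signed-mean scale scores and mapped criteria,
        computed from the precomputed covariances."""
        out: dict[tuple[str, str], float] = {}
        for factor, crit_ids in mapping.items():
            members = [i for i in selection if self.item_factor[i] == factor]
            if not members:
                raise PoolError(f"no selected items for factor {factor!r}")
            idx = self.index_of(members)
            s = np.array([self.item_sign[i] for i in members], float)
            var_score = float(s @ self.item_cov[np.ix_(idx, idx)] @ s)
            for cid in crit_ids:
                c = self.criterion_ids.index(cid)
                cov = float(s @ self.item_crit_cov[idx, c])
                out[(factor, cid)] = cov / np.sqrt(var_score * self.crit_var[c])
        return out


def _evaluate(
    selection: Sequence[str],
    ctx: EvaluationContext,
    obj_config: ObjectiveConfig,
    items_per_facet: int = 2,
) -> EvaluatedSolution:
    selection = tuple(selection)
    model = build_selection_model(selection, ctx.pool, items_per_facet)
    sub = ctx.moments.subset(ctx.index_of(selection))
    fit = fit_ml(model, sub)
    if not (fit.converged and fit.admissible):
        obj = composite_objective(fit, None, None, None, obj_config)
        return EvaluatedSolution(selection, obj, None, None, None)
    indices = fit_indices(fit, sub, model)
    signs = {iid: ctx.item_sign[iid] for iid in selection}
    omegas = [
        mcdonald_omega(
            fit, model, f, signs,
            include_residual_cov=obj_config.omega_include_residual_cov,
        )
        for f in model.factor_names
    ]
    corrs = ctx.score_criterion_corr(selection, obj_config.criterion_mapping)
    obj = composite_objective(fit, indices, omegas, corrs, obj_config)
    return EvaluatedSolution(selection, obj, indices, omegas, corrs)


def evaluate_candidate(
    selection: Sequence[str],
    responses: ResponseMatrix,
    criteria: CriterionTable,
    pool: ItemPool,
    obj_config: ObjectiveConfig | None = None,
    items_per_facet: int = 2,
) -> EvaluatedSolution:
    """Score one feasible selection: CFA fit, indices, omega, validity,
    composite.  Deterministic given inputs."""
    ctx = EvaluationContext(pool, responses, criteria)
    return _evaluate(selection, ctx, obj_config or ObjectiveConfig(), items_per_facet)


# ---------------------------------------------------------------------------
# pheromone mechanics


def initialize_state(pool: ItemPool, config: ACOConfig) -> PheromoneState:
    for facet in pool.facets:
        k = len(pool.items_of_facet(facet))
        if k < config.items_per_facet:
            raise PoolError(
                f"facet {facet!r} has {k} candidates, fewer than "
                f"items_per_facet={config.items_per_facet}"
            )
    return PheromoneState(
        pool=pool,
        pheromone={iid: 1.0 for iid in pool.item_ids},
        items_per_facet=config.items_per_facet,
    )


def construct_solution(state: PheromoneState, rng: np.random.Generator) -> tuple[str, ...]:
    """Sequential pheromone-proportional draws without replacement, per facet."""
    chosen: list[str] = []
    for facet in state.pool.facets:
        ids = [it.item_id for it in state.pool.items_of_facet(facet)]
        weights = [state.pheromone[i] for i in ids]
        for _ in range(state.items_per_facet):
            total = sum(weights)
            r = rng.random() * total
            acc = 0.0
            pick = len(ids) - 1
            for idx, w in enumerate(weights):
                acc += w
                if r < acc:
                    pick = idx
                    break
            chosen.append(ids.pop(pick))
            weights.pop(pick)
    return tuple(chosen)


def _better(a: EvaluatedSolution, b: EvaluatedSolution | None) -> bool:
    """True if *a* beats *b* (higher composite; ties go to the
    lexicographically smaller sorted item tuple)."""
    if b is None:
        return True
    if a.composite != b.composite:
        return a.composite > b.composite
    return tuple(sorted(a.selection)) < tuple(sorted(b.selection))


def update_pheromone(
    state: PheromoneState, iteration_best: EvaluatedSolution, config: ACOConfig
) -> PheromoneState:
    """Evaporate, then deposit the iteration-best composite on its items."""
    rho = config.evaporation
    in_best = set(iteration_best.selection)
    for iid in state.pheromone:
        phi = (1.0 - rho) * state.pheromone[iid]
        if iid in in_best:
            phi += iteration_best.composite
        state.pheromone[iid] = max(phi, PHEROMONE_FLOOR)
    if iteration_best.composite > 0 and _better(iteration_best, state.global_best):
        state.global_best = iteration_best
    state.iteration += 1
    return state


# ---------------------------------------------------------------------------
# search drivers


def run_aco(
    pool: ItemPool,
    responses: ResponseMatrix,
    criteria: CriterionTable,
    aco_config: ACOConfig | None = None,
    obj_config: ObjectiveConfig | None = None,
    cache: dict | None = None,
) -> ACOResult:
    """Multi-run ant-colony search; returns the best solution over all runs
    plus per-run bests and a per-iteration trace."""
    aco_config = aco_config or ACOConfig()
    obj_config = obj_config or ObjectiveConfig()
    ctx = EvaluationContext(pool, responses, criteria)
    cache = {} if cache is None else cache
    n_evals = 0
    trace: list[dict] = []
    run_bests: list[EvaluatedSolution] = []

    for run_idx, seed in enumerate(aco_config.run_seeds()):
        rng = np.random.default_rng(seed)
        state = initialize_state(pool, aco_config)
        stagnation = 0
        for it in range(aco_config.max_iterations):
            iteration_best: EvaluatedSolution | None = None
            for _ in range(aco_config.n_ants):
                sel = construct_solution(state, rng)
                key = tuple(sorted(sel))
                sol = cache.get(key)
                if sol is None:
                    sol = _evaluate(sel, ctx, obj_config, aco_config.items_per_facet)
                    cache[key] = sol
                n_evals += 1
                if _better(sol, iteration_best):
                    iteration_best = sol
            prev = state.global_best
            update_pheromone(state, iteration_best, aco_config)
            improved = (
                state.global_best is not None
                and (prev is None or state.global_best.composite > prev.composite)
            )
            stagnation = 0 if improved else stagnation + 1
            trace.append({
                "run": run_idx,
                "iteration": it,
                "iteration_best": iteration_best.composite,
                "global_best": (
                    state.global_best.composite if state.global_best else None
                ),
            })
            logger.info(
                "run %d iter %d: iteration best %.4f, global best %s",
                run_idx, it, iteration_best.composite,
                f"{state.global_best.composite:.4f}" if state.global_best else "-",
            )
            if stagnation >= aco_config.stop_stagnation:
                break
        if state.global_best is None:
            # every candidate degenerate: keep the last iteration best anyway
            state.global_best = iteration_best
        best = EvaluatedSolution(
            state.global_best.selection, state.global_best.objective,
            state.global_best.indices, state.global_best.omegas,
            state.global_best.correlations,
            seed=_seed_repr(seed), iteration=state.iteration,
        )
        run_bests.append(best)

    overall = run_bests[0]
    for cand in run_bests[1:]:
        if _better(cand, overall):
            overall = cand
    return ACOResult(
        best=overall, run_bests=run_bests, trace=trace,
        n_evaluations=n_evals, n_distinct_evaluations=len(cache),
    )


def _seed_repr(seed) -> object:
    if isinstance(seed, np.random.SeedSequence):
        return list(map(int, seed.entropy if isinstance(seed.entropy, tuple)
                        else [seed.entropy])) + list(seed.spawn_key)
    return seed


def exhaustive_search(
    pool: ItemPool,
    responses: ResponseMatrix,
    criteria: CriterionTable,
    obj_config: ObjectiveConfig | None = None,
    items_per_facet: int = 2,
    cap: int = 10_000,
    cache: dict | None = None,
) -> EvaluatedSolution:
    """Evaluate every feasible selection; argmax composite with
    lexicographic tie-breaking.  Guarded by a combinatorial cap."""
    obj_config = obj_config or ObjectiveConfig()
    per_facet: list[list[tuple[str, ...]]] = []
    total = 1
    for facet in pool.facets:
        ids = [it.item_id for it in pool.items_of_facet(facet)]
        combos = list(itertools.combinations(ids, items_per_facet))
        if not combos:
            raise PoolError(f"facet {facet!r} cannot supply {items_per_facet} items")
        per_facet.append(combos)
        total *= len(combos)
    if total > cap:
        raise PoolError(
            f"{total} feasible selections exceed the cap of {cap}; "
            "reduce the pool or raise the cap"
        )
    ctx = EvaluationContext(pool, responses, criteria)
    cache = {} if cache is None else cache
    best: EvaluatedSolution | None = None
    for parts in itertools.product(*per_facet):
        sel = tuple(itertools.chain.from_iterable(parts))
        key = tuple(sorted(sel))
        sol = cache.get(key)
        if sol is None:
            sol = _evaluate(sel, ctx, obj_config, items_per_facet)
            cache[key] = sol
        if _better(sol, best):
            best = sol
    return best


def cross_validate(
    final: EvaluatedSolution,
    validation_responses: ResponseMatrix,
    validation_criteria: CriterionTable,
    pool: ItemPool,
    obj_config: ObjectiveConfig | None = None,
    items_per_facet: int = 2,
    degradation_margin: float = 0.15,
) -> ValidationReport:
    """Refit the selected model on an independent sample.

    The report pairs the selection-sample snapshot with the validation
    values and flags degradation when the validation fit is degenerate or
    the composite drops by more than ``degradation_margin``.
    """
    missing = [i for i in final.selection
               if i not in validation_responses.item_ids]
    if missing:
        raise PoolError(f"selection items absent from validation data: {missing}")
    val = evaluate_candidate(
        final.selection, validation_responses, validation_criteria, pool,
        obj_config, items_per_facet,
    )
    degraded = bool(
        val.objective.degenerate
        or final.composite - val.composite > degradation_margin
    )
    return ValidationReport(
        selection=final.selection,
        selection_sample=final,
        validation_sample=val,
        degraded=degraded,
        degradation_margin=degradation_margin,
    )
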