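"""Ant-colony mechanics: construction probabilities, pheromone updates,
trace invariants, oracle and random-search comparisons."""

import itertools

import numpy as np
import pytest
from scipy import stats

from facetforge.aco import (ACOConfig, EvaluationContext, PheromoneState,
                            construct_solution, cross_validate,
                            evaluate_candidate, exhaustive_search,
                            initialize_state, run_aco, update_pheromone,
                            EvaluatedSolution, _evaluate)
from facetforge.item_model import PoolError
from facetforge.objective import ObjectiveConfig, ObjectiveValue
from facetforge.simulate import default_population_spec, simulate_responses
from tests.conftest import make_toy_pool


def _state_with(pool, phero, items_per_facet=2):
    st_ = initialize_state(pool, ACOConfig(items_per_facet=items_per_facet))
    st_.pheromone.update(phero)
    return st_


def _fake_solution(selection, composite):
    return EvaluatedSolution(
        tuple(selection),
        ObjectiveValue(composite, composite, composite, composite,
                       degenerate=composite == 0.0),
        None, None, None,
    )


# ---------------------------------------------------------------------------
# state & construction


def test_initialize_state(pool52):
    st_ = initialize_state(pool52, ACOConfig())
    assert len(st_.pheromone) == 52
    assert all(v == 1.0 for v in st_.pheromone.values())


def test_initialize_state_infeasible():
    pool = make_toy_pool(items_per_facet_pool=1)
    with pytest.raises(PoolError, match="fewer than"):
        initialize_state(pool, ACOConfig())


def test_construct_uniform_pair_probabilities(toy_pool):
    """Sequential weighted draws without replacement: with uniform
    pheromone each of the C(4,2)=6 pairs per facet is equally likely.
    Oracle: the closed-form two-draw probability
    P{i,j} = w_i/W * w_j/(W-w_i) + w_j/W * w_i/(W-w_j)."""
    w = {f"fa_{i}": 1.0 for i in range(1, 5)}
    W = sum(w.values())
    probs = {}
    for i, j in itertools.combinations(sorted(w), 2):
        probs[(i, j)] = (w[i] / W) * (w[j] / (W - w[i])) + \
                        (w[j] / W) * (w[i] / (W - w[j]))
    assert all(abs(p - 1 / 6) < 1e-12 for p in probs.values())

    st_ = initialize_state(toy_pool, ACOConfig())
    rng = np.random.default_rng(0)
    counts = {pair: 0 for pair in probs}
    n = 12_000
    for _ in range(n):
        sel = construct_solution(st_, rng)
        pair = tuple(sorted(s for s in sel if s.startswith("fa")))
        counts[pair] += 1
    freqs = np.array([counts[p] / n for p in probs])
    assert np.abs(freqs - 1 / 6).max() < 0.02


def test_construct_extreme_pheromone(toy_pool):
    st_ = _state_with(toy_pool, {
        "fa_1": 1e6, "fa_2": 1e6, "fa_3": 1e-6, "fa_4": 1e-6,
    })
    rng = np.random.default_rng(1)
    for _ in range(200):
        sel = construct_solution(st_, rng)
        assert {"fa_1", "fa_2"} <= set(sel)


def test_construct_forced_facet():
    pool = make_toy_pool(items_per_facet_pool=2)
    st_ = initialize_state(pool, ACOConfig())
    rng = np.random.default_rng(2)
    sel = construct_solution(st_, rng)
    assert set(sel) == {f"{f}_{i}" for f in ("fa", "fb", "fc") for i in (1, 2)}


# ---------------------------------------------------------------------------
# pheromone update


def test_update_rule_deposit_and_evaporation(toy_pool):
    st_ = initialize_state(toy_pool, ACOConfig(evaporation=0.0))
    best = _fake_solution(["fa_1", "fa_2", "fb_1", "fb_2", "fc_1", "fc_2"], 0.6)
    update_pheromone(st_, best, ACOConfig(evaporation=0.0))
    assert st_.pheromone["fa_1"] == pytest.approx(1.6)
    assert st_.pheromone["fa_3"] == pytest.approx(1.0)

    st2 = initialize_state(toy_pool, ACOConfig(evaporation=0.1))
    update_pheromone(st2, best, ACOConfig(evaporation=0.1))
    assert st2.pheromone["fa_3"] == pytest.approx(0.9)
    assert st2.pheromone["fa_1"] == pytest.approx(0.9 + 0.6)


def test_update_with_degenerate_best_keeps_global(toy_pool):
    st_ = initialize_state(toy_pool, ACOConfig(evaporation=0.1))
    good = _fake_solution(["fa_1", "fa_2", "fb_1", "fb_2", "fc_1", "fc_2"], 0.5)
    update_pheromone(st_, good, ACOConfig(evaporation=0.1))
    bad = _fake_solution(["fa_3", "fa_4", "fb_3", "fb_4", "fc_3", "fc_4"], 0.0)
    update_pheromone(st_, bad, ACOConfig(evaporation=0.1))
    assert st_.global_best.selection == good.selection
    # degenerate best: evaporation only
    assert st_.pheromone["fa_3"] == pytest.approx(0.9 * 0.9)


# ---------------------------------------------------------------------------
# evaluation


def test_evaluate_planted_beats_weak(toy_pool, toy_data, obj_config):
    resp, crit, truth = toy_data
    strong = _evaluate(tuple(truth.planted_items),
                       EvaluationContext(toy_pool, resp, crit), obj_config)
    weak_sel = tuple(f"{f}_{i}" for f in ("fa", "fb", "fc") for i in (3, 4))
    weak = _evaluate(weak_sel, EvaluationContext(toy_pool, resp, crit), obj_config)
    assert 0.0 <= weak.composite <= 1.0
    assert strong.composite > weak.composite


def test_evaluate_matches_scorer_route(toy_pool, toy_data, obj_config):
    """Covariance-algebra criterion correlations equal the direct
    score-and-correlate route."""
    from facetforge.item_model import scale_memberships
    from facetforge.reliability import criterion_correlations, score_scales

    resp, crit, truth = toy_data
    sol = evaluate_candidate(truth.planted_items, resp, crit, toy_pool, obj_config)
    members = scale_memberships(toy_pool, truth.planted_items, "three")
    scores = score_scales(resp, members)
    direct = criterion_correlations(scores, crit, obj_config.criterion_mapping)
    for key, r in direct.items():
        assert sol.correlations[key] == pytest.approx(r, abs=1e-10)


# ---------------------------------------------------------------------------
# search drivers


def test_run_aco_trace_invariants(toy_pool, toy_data):
    resp, crit, _ = toy_data
    cfg = ACOConfig(n_ants=10, stop_stagnation=5, n_runs=2, base_seed=3)
    res = run_aco(toy_pool, resp, crit, cfg, ObjectiveConfig())
    # global best non-decreasing within each run
    for run in (0, 1):
        series = [t["global_best"] for t in res.trace if t["run"] == run]
        assert all(b >= a - 1e-15 for a, b in zip(series, series[1:]))
    # every solution satisfies the per-facet constraint
    for sol in res.run_bests:
        facets = [s.rsplit("_", 1)[0] for s in sol.selection]
        assert all(facets.count(f) == 2 for f in ("fa", "fb", "fc"))


def test_run_aco_degenerate_config(toy_pool, toy_data):
    resp, crit, _ = toy_data
    cfg = ACOConfig(n_ants=1, stop_stagnation=1, max_iterations=1, n_runs=1,
                    base_seed=0)
    res = run_aco(toy_pool, resp, crit, cfg, ObjectiveConfig())
    assert res.n_evaluations == 1
    assert len(res.trace) == 1


def test_run_aco_reproducible(toy_pool, toy_data):
    resp, crit, _ = toy_data
    cfg = ACOConfig(n_ants=8, stop_stagnation=4, n_runs=2, base_seed=12)
    r1 = run_aco(toy_pool, resp, crit, cfg, ObjectiveConfig())
    r2 = run_aco(toy_pool, resp, crit, cfg, ObjectiveConfig())
    assert r1.best.selection == r2.best.selection
    assert r1.trace == r2.trace


def test_exhaustive_counts_and_guard(toy_pool, toy_data):
    resp, crit, _ = toy_data
    cache = {}
    best = exhaustive_search(toy_pool, resp, crit, ObjectiveConfig(), cache=cache)
    assert len(cache) == 216
    assert best.composite == max(s.composite for s in cache.values())
    with pytest.raises(PoolError, match="cap"):
        exhaustive_search(toy_pool, resp, crit, ObjectiveConfig(), cap=100)


def test_exhaustive_single_choice():
    pool = make_toy_pool(items_per_facet_pool=2)
    spec, _ = default_population_spec(pool)
    resp, crit, _ = simulate_responses(spec, 300, seed=21)
    best = exhaustive_search(pool, resp, crit, ObjectiveConfig())
    assert sorted(best.selection) == sorted(pool.item_ids)


def test_aco_dominates_random_search(obj_config):
    """Paired seeds on a larger toy pool: equal-budget uniform random search
    should not beat the pheromone-guided search (one-sided sign test)."""
    pool = make_toy_pool(items_per_facet_pool=6)     # 15^3 = 3375 subsets
    spec, _ = default_population_spec(pool)
    resp, crit, _ = simulate_responses(spec, 400, seed=31)
    cache = {}
    ctx = EvaluationContext(pool, resp, crit)
    wins, losses = 0, 0
    for seed in range(20):
        cfg = ACOConfig(n_ants=10, stop_stagnation=5, max_iterations=40,
                        n_runs=1, seeds=[seed])
        res = run_aco(pool, resp, crit, cfg, obj_config, cache=cache)
        rng = np.random.default_rng(10_000 + seed)
        st_ = initialize_state(pool, cfg)
        rand_best = -np.inf
        for _ in range(res.n_evaluations):
            sel = construct_solution(st_, rng)       # uniform: no updates
            key = tuple(sorted(sel))
            sol = cache.get(key)
            if sol is None:
                sol = _evaluate(sel, ctx, obj_config)
                cache[key] = sol
            rand_best = max(rand_best, sol.composite)
        if res.best.composite > rand_best + 1e-12:
            wins += 1
        elif rand_best > res.best.composite + 1e-12:
            losses += 1
    assert wins > losses
    p = stats.binomtest(wins, wins + losses, alternative="greater").pvalue \
        if wins + losses else 1.0
    assert p < 0.05


# ---------------------------------------------------------------------------
# cross-validation


def test_cross_validation_identity(toy_pool, toy_data, obj_config):
    resp, crit, truth = toy_data
    sel_eval = evaluate_candidate(truth.planted_items, resp, crit, toy_pool,
                                  obj_config)
    rep = cross_validate(sel_eval, resp, crit, toy_pool, obj_config)
    assert rep.validation_sample.composite == pytest.approx(sel_eval.composite)
    assert not rep.degraded


def test_cross_validation_missing_items(toy_pool, toy_data, obj_config):
    resp, crit, truth = toy_data
    sel_eval = evaluate_candidate(truth.planted_items, resp, crit, toy_pool,
                                  obj_config)
    reduced = resp.subset([i for i in resp.item_ids if i != "fa_1"])
    with pytest.raises(PoolError, match="absent"):
        cross_validate(sel_eval, reduced, crit, toy_pool, obj_config)
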