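"""Shared fixtures: bundled pool, a toy 3-facet pool, and session-scoped
synthetic data sets so expensive simulations are generated once."""

from __future__ import annotations

import numpy as np
import pytest

from facetforge import (ObjectiveConfig, apply_pool_filters, load_bundled_pool,
                        default_population_spec, simulate_responses)
from facetforge.aco import EvaluationContext
from facetforge.item_model import FactorMap, Item, ItemPool


@pytest.fixture(scope="session")
def full_pool():
    return load_bundled_pool()


@pytest.fixture(scope="session")
def pool52(full_pool):
    return apply_pool_filters(full_pool)


@pytest.fixture(scope="session")
def population(full_pool):
    """Default planted-structure population over the full 60-item pool."""
    return default_population_spec(full_pool)


@pytest.fixture(scope="session")
def sim1000(population, pool52):
    """n=1000 synthetic selection sample, restricted to the filtered pool."""
    spec, truth = population
    resp, crit, latents = simulate_responses(spec, 1000, seed=1)
    return resp.subset(pool52.item_ids), crit, truth


@pytest.fixture(scope="session")
def ctx1000(pool52, sim1000):
    resp, crit, _ = sim1000
    return EvaluationContext(pool52, resp, crit)


def make_toy_pool(items_per_facet_pool: int = 4) -> ItemPool:
    """3 facets (one per factor) x 4 items: 216 feasible 2-per-facet sets."""
    facets = ("fa", "fb", "fc")
    items = tuple(
        Item(f"{f}_{i}", f) for f in facets for i in range(1, items_per_facet_pool + 1)
    )
    map3 = FactorMap(
        ("agentic", "antagonistic", "neurotic"),
        {"fa": "agentic", "fb": "antagonistic", "fc": "neurotic"},
        {"fa": 1, "fb": 1, "fc": 1},
    )
    map2 = FactorMap(
        ("grandiose", "vulnerable"),
        {"fa": "grandiose", "fb": "grandiose", "fc": "vulnerable"},
        {"fa": 1, "fb": 1, "fc": 1},
    )
    return ItemPool(items, facets, map3, map2)


@pytest.fixture(scope="session")
def toy_pool():
    return make_toy_pool()


@pytest.fixture(scope="session")
def toy_data(toy_pool):
    spec, truth = default_population_spec(toy_pool)
    resp, crit, _ = simulate_responses(spec, 500, seed=11)
    return resp, crit, truth


@pytest.fixture(scope="session")
def obj_config():
    return ObjectiveConfig()
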