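# facetforge

Short-form questionnaire construction by **ant-colony item selection**
over a confirmatory factor model.

Multi-facet personality inventories (the bundled example is shaped like a
15-facet narcissism inventory with agentic, antagonistic and neurotic
factors) are often too long for applied use. Classical abbreviation picks
items by statistics computed on the full instrument, but model fit,
composite reliability and criterion validity are properties of the
*selected subset*. `facetforge` searches the constrained subset space
directly: every candidate brief form (a fixed number of items per facet)
is scored by fitting a three-correlated-factor model with within-facet
residual correlations by maximum likelihood,

    F_ML(θ) = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − p,    Σ = ΛΦΛ′ + Θ,

and evaluating a composite objective: logistic transforms (onto 0–1) of

1. **model fit** — RMSEA, CFI, SRMR;
2. **reliability** — McDonald's ω (factor saturation) per factor;
3. **validity** — Pearson correlations of the factor scale scores with
   mapped external criteria;

averaged within and across the three groups. A pheromone-guided search
(default: 50 candidate models per iteration, stop after 30 iterations
without improvement, best of 10 seeded runs) reinforces items that appear
in high-scoring subsets, and the final selection is re-estimated on an
independent validation sample. A synthetic-data generator with planted
ground truth (known best items, known factor correlations, known
criterion validities) makes the whole pipeline testable without any real
data; an exhaustive-search oracle verifies the metaheuristic on small
pools.

For the model, estimation details, objective anchors and generator
assumptions, see [docs/methods.md](docs/methods.md).

## Worked example

```python
from facetforge import (ACOConfig, ObjectiveConfig, apply_pool_filters,
                        default_population_spec, load_bundled_pool,
                        run_aco, simulate_responses)

pool_full = load_bundled_pool()
pool = apply_pool_filters(pool_full)          # 60 -> 52 candidates
spec, truth = default_population_spec(pool_full)
responses, criteria, _ = simulate_responses(spec, n=1000, seed=7)
responses = responses.subset(pool.item_ids)

result = run_aco(pool, responses, criteria,
                 ACOConfig(n_ants=50, stop_stagnation=30, n_runs=3, base_seed=7),
                 ObjectiveConfig())
best = result.best
print(f"selected {len(best.selection)} items, composite = {best.composite:.3f}")
print(f"RMSEA = {best.indices.rmsea:.3f}, CFI = {best.indices.cfi:.3f}, "
      f"SRMR = {best.indices.srmr:.3f}")
print("omega:", {o.scale_id: round(o.coefficient, 3) for o in best.omegas})
overlap = len(set(truth.planted_items) & set(best.selection)) / 30
print(f"overlap with planted best subset: {overlap:.0%}")
```

Output:

```
selected 30 items, composite = 0.864
RMSEA = 0.000, CFI = 1.000, SRMR = 0.021
omega: {'agentic': 0.903, 'antagonistic': 0.939, 'neurotic': 0.873}
overlap with planted best subset: 93%
```

Reading this: the search returned a feasible 30-item brief form (2 items
per facet of 15). The three-factor model fits the selected items
essentially perfectly (the synthetic population satisfies the model, so
RMSEA ≈ 0 for a good subset), factor saturation is high because the
planted "strong" items carry loadings of .80, and 28 of the 30 planted
best items were recovered. The composite (0–1) is the quantity the
colony maximizes.

The same workflow is available from the shell:

```bash
facetforge simulate --n 1000 --seed 7 --out scratch/demo
facetforge select --responses scratch/demo_responses.csv \
    --criteria scratch/demo_criteria.csv --runs 3 --seed 7 \
    --out scratch/result.json
facetforge pipeline --out scratch/pipeline_out   # full two-sample workflow
```

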