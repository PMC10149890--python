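# Methods

## The problem

Short forms of multi-facet questionnaires are usually assembled from
item-level statistics computed on the *full* instrument (loadings,
discriminations), even though the properties one actually cares about —
model fit, composite reliability, criterion validity — are properties of
the *selected subset* and change once items are removed. `facetforge`
treats abbreviation as a combinatorial optimization problem: given a pool
of items organized into narrow facets that load on a small number of broad
correlated factors, find the subset (a fixed number of items per facet)
that maximizes a composite of subset-level criteria, and confirm the
result on an independent sample.

The reference instrument shape is a 15-facet narcissism inventory: facets
assigned 4/8/3 to agentic, antagonistic, and neurotic factors (three-factor
scoring) or 11/4 to grandiose/vulnerable factors (two-factor scoring), a
60-item pool filtered to 52 candidates (content-redundant and lone
reverse-keyed items removed), and a 30-item target (2 items per facet).
The package is instrument-agnostic: pools, maps and flags come from a YAML
spec.

## Measurement model

Candidate subsets are scored under a three-correlated-factor model
estimated on the item correlation matrix by maximum likelihood,

F_ML(θ) = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − p,

with Σ = ΛΦΛ′ + Θ. Each item loads only on its facet's factor; each
same-facet item pair gets a free residual covariance θ_ij, which absorbs
facet-specific shared variance (equivalent to nested orthogonal facet
factors and more robust, with two indicators per facet, than a
facet-level higher-order model). Identification is by unit factor
variances, so all loadings are free and candidate subsets are treated
symmetrically. For a 15-facet, 30-item subset this gives 30 loadings + 3
factor correlations + 30 residual variances + 15 residual covariances =
78 free parameters, df = 465 − 78 = 387.

Hierarchical (factor→facet→item) and correlated-facets variants are
available for structure checks. In hierarchical models the first-order
facet variances are standardized and the disturbances are *derived*,
ψ_ii = 1 − (ΓΦΓ′)_ii, rather than freed with marker loadings; this keeps
every loading free and makes negative disturbances (Heywood cases)
directly visible.

### Numerical choices

- Analysis is on the correlation metric (the reliability and
  factor-correlation quantities of interest are standardized); χ² on
  correlations is the conventional approximation used by common SEM
  defaults.
- χ² = n·F_min (multiplier n, not n−1); RMSEA uses the same n. The
  dialect choice shifts third decimals at most.
- Start values are fixed (loadings 0.5, factor correlations 0.2, residual
  variances 0.75, residual covariances 0.05), so every fit is a
  deterministic function of its inputs. This matters: two evaluations of
  the same subset are bitwise identical, so the stochastic search and the
  exhaustive oracle can be compared at 1e-10.
- Optimization is quasi-Newton (L-BFGS-B) with analytic gradients
  (∂F/∂Λ = 2AΛΦ, ∂F/∂Φ = Λ′AΛ, ∂F/∂Θ = A with A = Σ⁻¹ − Σ⁻¹SΣ⁻¹), a
  convergence criterion of gradient max-norm ≤ 1e-6, and max 500
  iterations. Non-PD Σ during the search triggers a smallest-eigenvalue
  penalty step rather than an exception. The simple-structure first-order
  path is numba-compiled (~3–8 ms per 30-item fit); a pure-numpy generic
  path handles arbitrary patterns and hierarchies, and a test asserts the
  two paths compute the same function.
- Residual variances are *not* log-transformed: Heywood cases must remain
  representable, and a fit with any θ_ii < 0 or |correlation| > 1 is
  flagged inadmissible.
- Baseline (independence) model on correlations has the closed form
  F_b = −ln|S|, df_b = p(p−1)/2. For df = 0 models RMSEA is defined as 0
  and CFI as 1.
- SRMR averages squared residuals over i ≤ j (diagonal included; on the
  correlation metric diagonal residuals are near zero).

## Reliability and validity

Scales are scored as signed means of item ratings on the 1–5 metric
(reverse-keyed items recoded 6 − x at load; facets scored negatively
within a factor — indifference under neurotic narcissism — contribute
reversed). Cronbach's α comes from observed covariances. McDonald's ω
(factor saturation) comes from the fitted selection model:

ω = (Σᵢ sᵢλᵢ)² / ((Σᵢ sᵢλᵢ)² + Σᵢ θᵢᵢ + 2Σ_{i<j} sᵢsⱼθᵢⱼ),

with the within-facet residual covariances included in the error term by
default (`omega_include_residual_cov=False` reproduces the
loadings-plus-unique-variances version; the published pipeline does not
state which convention it used, so the toggle is exposed). Criterion
validity is the Pearson correlation between each factor's scale score and
its mapped external criteria (two agentic, three antagonistic, two
neurotic criteria). Group contrasts use Welch's t (always-on unequal
variance correction — conservative and simpler than "if applicable").

## The composite objective

Raw criteria live on incommensurable scales, so each is mapped to (0, 1)
by a logistic around a midpoint m with steepness s:
maximize: 1/(1 + exp(−(x − m)/s)); minimize mirrors it. Defaults put the
midpoints at conventional cutoffs — RMSEA (.05, s=.015, minimize), CFI
(.90, .03), SRMR (.08, .02, minimize), ω (.70, .05), validity r
(.50, .10) — and are configuration-exposed; they are this package's
defaults, not a claim about any published script's anchors. The fit
component averages the three index transforms, the reliability component
the three ω transforms, the validity component the seven correlation
transforms; the overall objective is the unweighted mean of the three
components. A non-converged or inadmissible fit scores the configured
floor (default 0), removing the candidate from reinforcement.

A solution sitting exactly at every midpoint scores 0.5, and the
composite is strictly increasing in every raw criterion — both asserted
as tests.

## The search

Pheromone weights φᵢ start at 1. Each ant draws, per facet independently,
`items_per_facet` distinct items sequentially with probability
φᵢ/Σ_facet φ — feasibility by construction, no rejection. After each
iteration of `n_ants` candidates, all weights evaporate by factor
(1 − ρ), ρ = 0.10, and the iteration-best candidate deposits its
composite on its items (floor 1e-6). A run stops after `stop_stagnation`
iterations without strict improvement of the global best (default 30, the
published stopping rule) or a hard cap of 500 iterations (an addition to
bound runtime on pathological objectives). The default configuration
evaluates 50 candidates per iteration and pools 10 independently seeded
runs, returning the overall best; ties break toward the lexicographically
smallest item tuple for determinism. Evaluations are memoized per data
set, so converged colonies (all ants proposing the same subset) cost
nothing.

An exhaustive oracle enumerates all Π_f C(k_f, m) feasible subsets (cap
10,000) for small pools; acceptance tests require the stochastic search
to reach the enumerated optimum in ≥ 95% of seeds on a 216-subset pool,
and to stochastically dominate an equal-budget uniform random search.

Cross-validation refits the selected model on an independent sample and
recomputes ω, validity and the composite; the report flags degradation
when the validation fit is degenerate or the composite drops by more than
a configurable margin (default 0.15 — large relative to sampling noise at
n ≈ 1,000, small relative to structural failure, where the reliability
and validity components collapse toward 0).

## Synthetic data

The generator draws three correlated content factors (default
correlations .51, .03, −.04 — the brief form's observed factor
intercorrelations), 15 mutually orthogonal facet nuisance factors (the
minimal structure justifying the within-facet residual covariances), and
independent residuals; item continua x = λ·factor + γ·facet + ε with unit
total variance are discretized to 1–5 by thresholds (−1.5, −.5, .5, 1.5).
Per facet, two "strong" items (|λ| = .80) are planted among "weak" ones
(|λ| = .45), all with γ = .30; facets scored negatively get negative λ,
mirroring the keyed direction of the real instrument. The planted strong
items are chosen among items that survive the pool filters, so the
ground-truth optimum is feasible. Criteria are generated from the latent
factors as r·f + √(1 − r²)·noise with population validities .65 (agentic),
.55 (antagonistic), .60 (neurotic).

What the generator does *not* emulate: cross-loadings, acquiescence and
careless responding, non-Gaussian latent distributions, missingness, and
the messier loading heterogeneity of real items. Consequently, passing
recovery tests shows the machinery is correct and the search effective
under the assumed structure — it does not certify performance on data
violating it. Synthetic reliability (ω ≈ .90) is higher than the .7–.8
typical for real short scales simply because the planted loadings are
clean; the separation between strong and weak items, not the absolute ω
level, is what the recovery tests exercise.

Problem sizes in the tests and the acceptance script (selection n = 1,823
and validation n = 1,098 in the acceptance script — the study-scale
sample sizes; n = 500–2,000 in tests) were chosen as realistic
desk-scale conditions for this design.

## Known limitations

- Likert items are treated as continuous under ML (the pipeline this
  mirrors did the same after WLSMV failed to converge); polychoric
  correlations are out of scope, so absolute fit statistics inherit
  categorization attenuation.
- No standard errors, robust test statistics, or modification indices —
  the engine estimates point solutions for subset comparison, not
  inferential SEM output.
- The bundled pool's item *identities* (which items are flagged
  redundant/reverse-keyed) are schematic placeholders; real applications
  should supply a pool spec with the instrument's published flags.
- The pheromone update rule (evaporation + iteration-best deposit) is one
  member of the ACO family; the published construction cites the ACO
  literature without printing its constants, so the rule and all constants
  are configuration, not fixed science.
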