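"""The composite optimization criterion for item selection.

Three heterogeneous criterion groups -- model fit (RMSEA, CFI, SRMR),
factor saturation (one omega per factor) and external validity (mapped
factor-criterion correlations) -- are made commensurable by a logistic
("logit") transform onto (0, 1) around conventional-cutoff midpoints, then
averaged within and across groups.  Candidate solutions whose factor model
did not converge or was inadmissible receive a fixed floor value (default
0) so the search cannot reinforce them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .cfa import FitIndices, FitResult
from .reliability import ReliabilityValue


@dataclass(frozen=True)
class LogitAnchor:
    midpoint: float
    scale: float
    direction: str = "maximize"     # "maximize" | "minimize"

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("anchor scale must be positive")
        if self.direction not in ("maximize", "minimize"):
            raise ValueError(f"bad direction {self.direction!r}")


# Conventional cutoffs as midpoints; exposed through the run configuration.
DEFAULT_ANCHORS: dict[str, LogitAnchor] = {
    "rmsea": LogitAnchor(0.05, 0.015, "minimize"),
    "cfi": LogitAnchor(0.90, 0.03, "maximize"),
    "srmr": LogitAnchor(0.08, 0.02, "minimize"),
    "omega": LogitAnchor(0.70, 0.05, "maximize"),
    "validity_r": LogitAnchor(0.50, 0.10, "maximize"),
}

# Factor -> external criterion columns whose correlation is maximized.
DEFAULT_CRITERION_MAPPING: dict[str, list[str]] = {
    "agentic": ["npi_leadership_authority", "narq_admiration"],
    "antagonistic": ["npi_entitlement_exploitativeness", "narq_rivalry", "pes"],
    "neurotic": ["hsns", "pni_vulnerability"],
}


@dataclass
class ObjectiveConfig:
    anchors: dict[str, LogitAnchor] = field(
        default_factory=lambda: dict(DEFAULT_ANCHORS)
    )
    criterion_mapping: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CRITERION_MAPPING.items()}
    )
    nonconvergence_value: float = 0.0
    omega_include_residual_cov: bool = True

    def __post_init__(self) -> None:
        missing = set(DEFAULT_ANCHORS) - set(self.anchors)
        if missing:
            raise ValueError(f"missing anchors: {sorted(missing)}")
        if not 0.0 <= self.nonconvergence_value < 1.0:
            raise ValueError("nonconvergence_value must lie in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "anchors": {
                k: {"midpoint": a.midpoint, "scale": a.scale, "direction": a.direction}
                for k, a in self.anchors.items()
            },
            "criterion_mapping": self.criterion_mapping,
            "nonconvergence_value": self.nonconvergence_value,
            "omega_include_residual_cov": self.omega_include_residual_cov,
        }


@dataclass
class ObjectiveValue:
    fit_component: float
    reliability_component: float
    validity_component: float
    composite: float
    degenerate: bool = False        # non-converged / inadmissible fit

    def to_dict(self) -> dict:
        return {
            "fit_component": self.fit_component,
            "reliability_component": self.reliability_component,
            "validity_component": self.validity_component,
            "composite": self.composite,
            "degenerate": self.degenerate,
        }


def logistic_unit(x: float, anchor: LogitAnchor) -> float:
    """Strictly monotone map of a raw criterion onto (0, 1).

    The midpoint maps to 0.5; 'minimize' flips the direction so that better
    raw values always map toward 1.
    """
    z = (x - anchor.midpoint) / anchor.scale
    if anchor.direction == "minimize":
        z = -z
    # numerically stable logistic
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def fit_component(indices: FitIndices, config: ObjectiveConfig) -> float:
    vals = (
        logistic_unit(indices.rmsea, config.anchors["rmsea"]),
        logistic_unit(indices.cfi, config.anchors["cfi"]),
        logistic_unit(indices.srmr, config.anchors["srmr"]),
    )
    return sum(vals) / 3.0


def reliability_component(
    omegas: list[ReliabilityValue], config: ObjectiveConfig
) -> float:
    if not omegas:
        raise ValueError("at least one omega value required")
    a = config.anchors["omega"]
    return sum(logistic_unit(o.coefficient, a) for o in omegas) / len(omegas)


def validity_component(
    correlations: dict[tuple[str, str], float], config: ObjectiveConfig
) -> float:
    a = config.anchors["validity_r"]
    vals = []
    for factor, crit_ids in config.criterion_mapping.items():
        for cid in crit_ids:
            if (factor, cid) not in correlations:
                raise ValueError(f"missing mapped correlation ({factor!r}, {cid!r})")
            vals.append(logistic_unit(correlations[(factor, cid)], a))
    return sum(vals) / len(vals)


def composite_objective(
    solution_fit: FitResult | None,
    indices: FitIndices | None,
    omegas: list[ReliabilityValue] | None,
    correlations: dict[tuple[str, str], float] | None,
    config: ObjectiveConfig,
) -> ObjectiveValue:
    """Average of the three unit-interval components.

    A non-converged or inadmissible CFA yields the configured floor value
    with all components flagged degenerate, removing the candidate from
    pheromone reinforcement.
    """
    if solution_fit is not None and not (
        solution_fit.converged and solution_fit.admissible
    ):
        v = config.nonconvergence_value
        return ObjectiveValue(v, v, v, v, degenerate=True)
    f = fit_component(indices, config)
    r = reliability_component(omegas, config)
    v = validity_component(correlations, config)
    return ObjectiveValue(f, r, v, (f + r + v) / 3.0)
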