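"""End-to-end orchestration: simulate -> filter -> select -> cross-validate
-> report.

The pipeline mirrors a two-sample short-form construction workflow: the
brief form is selected on one sample, its fit/reliability/validity are
re-estimated on an independently collected sample, and the brief-form scale
scores are compared with the full-pool scores.  Reports are written both as
JSON (full precision) and Markdown (display rounding).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import yaml

from .aco import ACOConfig, ACOResult, cross_validate, run_aco
from .item_model import (CriterionTable, ItemPool, ResponseMatrix,
                         apply_pool_filters, load_bundled_pool, load_criteria,
                         load_item_pool, load_responses, scale_memberships)
from .objective import ObjectiveConfig, LogitAnchor
from .reliability import cronbach_alpha, score_scales
from .simulate import default_population_spec, simulate_responses

logger = logging.getLogger(__name__)


@dataclass
class SimulationSpec:
    n_selection: int = 1823
    n_validation: int = 1098
    seed: int = 0


@dataclass
class PipelineConfig:
    pool_file: str | None = None            # None -> bundled schematic pool
    responses_file: str | None = None
    criteria_file: str | None = None
    validation_responses_file: str | None = None
    validation_criteria_file: str | None = None
    simulation: SimulationSpec | None = None
    aco: ACOConfig = field(default_factory=ACOConfig)
    objective: ObjectiveConfig = field(default_factory=ObjectiveConfig)
    drop_redundant: bool = True
    drop_reverse: bool = True
    out_dir: str | None = None

    def __post_init__(self) -> None:
        has_data = self.responses_file is not None
        if not has_data and self.simulation is None:
            self.simulation = SimulationSpec()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.get("simulation")
        aco_raw = raw.get("aco", {})
        obj_raw = raw.get("objective", {})
        anchors = obj_raw.pop("anchors", None)
        obj = ObjectiveConfig(**obj_raw) if obj_raw or anchors is None else ObjectiveConfig(**obj_raw)
        if anchors:
            for key, a in anchors.items():
                obj.anchors[key] = LogitAnchor(
                    a["midpoint"], a["scale"], a.get("direction", "maximize")
                )
        return cls(
            pool_file=raw.get("pool_file"),
            responses_file=raw.get("responses_file"),
            criteria_file=raw.get("criteria_file"),
            validation_responses_file=raw.get("validation_responses_file"),
            validation_criteria_file=raw.get("validation_criteria_file"),
            simulation=SimulationSpec(**sim) if sim else None,
            aco=ACOConfig(**aco_raw),
            objective=obj,
            drop_redundant=raw.get("drop_redundant", True),
            drop_reverse=raw.get("drop_reverse", True),
            out_dir=raw.get("out_dir"),
        )


def compare_forms(
    selection: list[str] | tuple[str, ...],
    responses: ResponseMatrix,
    pool: ItemPool,
    model_kind: str = "three",
) -> dict:
    """Per-factor Pearson r between brief-form and full-pool scale scores."""
    full = score_scales(responses, scale_memberships(pool, None, model_kind))
    brief_members = scale_memberships(pool, list(selection), model_kind)
    brief = score_scales(responses, brief_members)
    out = {}
    for factor in brief.scale_ids:
        r = float(np.corrcoef(full.column(factor), brief.column(factor))[0, 1])
        out[factor] = r
    out["mean"] = float(np.mean([out[f] for f in brief.scale_ids]))
    return out


def _load_or_simulate(config: PipelineConfig, pool_full: ItemPool):
    if config.responses_file is not None:
        sel_resp = load_responses(config.responses_file, pool_full)
        sel_crit = load_criteria(config.criteria_file)
        val_resp = val_crit = None
        if config.validation_responses_file:
            val_resp = load_responses(config.validation_responses_file, pool_full)
            val_crit = load_criteria(config.validation_criteria_file)
        return sel_resp, sel_crit, val_resp, val_crit, None
    sim = config.simulation
    spec, truth = default_population_spec(pool_full, config.aco.items_per_facet)
    sel_resp, sel_crit, _ = simulate_responses(spec, sim.n_selection, sim.seed)
    val_resp, val_crit, _ = simulate_responses(
        spec, sim.n_validation, sim.seed + 1
    )
    return sel_resp, sel_crit, val_resp, val_crit, truth


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run report (also written to
    ``out_dir`` as JSON and Markdown when configured)."""
    stage = "item_model"
    try:
        pool_full = (
            load_item_pool(config.pool_file) if config.pool_file
            else load_bundled_pool()
        )
        pool = apply_pool_filters(
            pool_full, config.drop_redundant, config.drop_reverse
        )
        stage = "data"
        sel_resp, sel_crit, val_resp, val_crit, truth = _load_or_simulate(
            config, pool_full
        )
        sel_resp_pool = sel_resp.subset([i for i in pool.item_ids
                                         if i in sel_resp.item_ids])
        stage = "aco_select"
        result: ACOResult = run_aco(
            pool, sel_resp_pool, sel_crit, config.aco, config.objective
        )
        best = result.best
        stage = "cross_validate"
        validation = None
        if val_resp is not None:
            val_resp_pool = val_resp.subset(
                [i for i in pool.item_ids if i in val_resp.item_ids]
            )
            validation = cross_validate(
                best, val_resp_pool, val_crit, pool, config.objective,
                config.aco.items_per_facet,
            )
        stage = "report"
        members = scale_memberships(pool, list(best.selection), "three")
        alphas = {
            factor: cronbach_alpha(sel_resp_pool, [i for i, _ in items]).coefficient
            for factor, items in members.items()
        }
        by_facet = {
            facet: [i for i in best.selection
                    if pool.item(i).facet == facet]
            for facet in pool.facets
        }
        report = {
            "version": _pkg_version("facetforge"),
            "pool": {
                "n_items_full": len(pool_full.items),
                "n_items_filtered": len(pool.items),
                "facets": list(pool.facets),
            },
            "selection": {
                "items": list(best.selection),
                "by_facet": by_facet,
                "n_items": len(best.selection),
            },
            "selection_sample": best.snapshot(),
            "validation_sample": (
                validation.validation_sample.snapshot() if validation else None
            ),
            "validation_degraded": validation.degraded if validation else None,
            "alpha": alphas,
            "brief_vs_full_pool_r": compare_forms(
                best.selection, sel_resp, pool_full
            ),
            "planted_overlap": (
                _planted_overlap(best.selection, truth) if truth else None
            ),
            "config": {
                "aco": config.aco.to_dict(),
                "objective": config.objective.to_dict(),
                "simulation": (
                    vars(config.simulation) if config.simulation else None
                ),
            },
            "n_evaluations": result.n_evaluations,
            "n_distinct_evaluations": result.n_distinct_evaluations,
            "run_best_composites": [s.composite for s in result.run_bests],
            "trace": result.trace,
        }
        validate_report(report)
        if config.out_dir:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            with open(out / "result.json", "w", encoding="utf-8") as fh:
                json.dump(report, fh, indent=2)
            (out / "report.md").write_text(render_markdown(report), encoding="utf-8")
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _planted_overlap(selection, truth) -> float:
    planted = set(truth.planted_items)
    return len(planted & set(selection)) / len(planted)


# ---------------------------------------------------------------------------
# report schema + rendering


def _schema_path() -> Path:
    return Path(__file__).parent / "data" / "report_schema.json"


def validate_report(report: dict) -> None:
    """Check the report against the shipped structural schema.

    A deliberately small validator (required keys plus scalar types); the
    schema file documents the full layout.
    """
    with open(_schema_path(), "r", encoding="utf-8") as fh:
        schema = json.load(fh)
    _check_node(report, schema, path="report")


_TYPES = {
    "object": dict, "array": list, "string": str,
    "number": (int, float), "integer": int, "boolean": bool,
}


def _check_node(value, schema: dict, path: str) -> None:
    t = schema.get("type")
    if t:
        allowed = _TYPES[t]
        if schema.get("nullable") and value is None:
            return
        if not isinstance(value, allowed) or (
            t == "number" and isinstance(value, bool)
        ):
            raise ValueError(f"{path}: expected {t}, got {type(value).__name__}")
    for key, sub in schema.get("properties", {}).items():
        if key in schema.get("required", []) and (
            not isinstance(value, dict) or key not in value
        ):
            raise ValueError(f"{path}: missing required key {key!r}")
        if isinstance(value, dict) and key in value:
            _check_node(value[key], sub, f"{path}.{key}")


def render_markdown(report: dict) -> str:
    """Human-readable summary with display rounding."""
    sel = report["selection"]
    ss = report["selection_sample"]
    lines = [
        "# Brief-form selection report",
        "",
        f"Pool: {report['pool']['n_items_full']} items, filtered to "
        f"{report['pool']['n_items_filtered']} candidates across "
        f"{len(report['pool']['facets'])} facets.",
        "",
        f"Selected {sel['n_items']} items "
        f"({report['config']['aco']['items_per_facet']} per facet).",
        "",
        "## Selection sample",
        _snapshot_md(ss),
    ]
    if report.get("validation_sample"):
        lines += ["", "## Validation sample", _snapshot_md(report["validation_sample"]),
                  "", f"Degraded: {report['validation_degraded']}"]
    bf = report.get("brief_vs_full_pool_r") or {}
    if bf:
        lines += ["", "## Brief form vs full pool scale scores"]
        lines += [f"- {k}: r = {v:.3f}" for k, v in bf.items()]
    if report.get("planted_overlap") is not None:
        lines += ["", f"Planted-best overlap: {report['planted_overlap']:.0%}"]
    lines += ["", "## Items per facet"]
    for facet, items in sel["by_facet"].items():
        lines.append(f"- {facet}: {', '.join(items)}")
    return "\n".join(lines) + "\n"


def _snapshot_md(snap: dict) -> str:
    fi = snap.get("fit_indices") or {}
    om = snap.get("omega") or {}
    obj = snap.get("objective") or {}
    parts = []
    if fi:
        parts.append(
            f"- Fit: RMSEA = {fi['rmsea']:.3f}, CFI = {fi['cfi']:.3f}, "
            f"SRMR = {fi['srmr']:.3f} (chi2 = {fi['chi_square']:.1f}, "
            f"df = {fi['df']})"
        )
    if om:
        parts.append(
            "- Omega: " + ", ".join(f"{k} = {v:.3f}" for k, v in om.items())
        )
    cc = snap.get("criterion_correlations") or {}
    if cc:
        mean_r = sum(cc.values()) / len(cc)
        parts.append(f"- Mean mapped criterion r = {mean_r:.3f}")
    if obj:
        parts.append(f"- Composite objective = {obj['composite']:.4f}")
    return "\n".join(parts)
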