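"""Run configuration: loading, validation, orchestration, CSV output.

A run config is a small YAML document layered over the packaged defaults::

    horizon: {start: 2011, end: 2035}
    dt: 0.25
    anchors: {pop40plus_2011: 17.0e6, pop40plus_2035: 24.0e6,
              pop70plus_2035: 8.0e6, copd_total_2011: 3.45e6}
    overrides:                  # dotted paths into the default parameter tree
      spirometry.uptake: 0.40
    scenarios:
      - {intervention: none}
      - {intervention: III, effect_size: 0.5}
    output_dir: results
    log_level: INFO

With no config at all, :func:`load_and_validate_config` yields the
published base case.  Validation materializes the full parameter set and
reports every invariant violation, not just the first.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .demography import default_demography
from .interventions import (IncrementalResult, ScenarioSpec,
                            compare_scenarios, run_scenario)
from .model import ProjectionResult, simulate
from .params import (CalibrationAnchors, ParamSet, ParameterError,
                     build_paramset, load_raw_defaults)
from .sensitivity import one_way_sensitivity

logger = logging.getLogger(__name__)

DEFAULT_SCENARIOS = [ScenarioSpec("none")] + [
    ScenarioSpec(i, e) for i in ("I", "II", "III") for e in (0.10, 0.25, 0.50)
]


class ConfigError(ValueError):
    """A config that fails schema or invariant validation."""


@dataclass
class RunConfig:
    """A validated, fully materialized run configuration."""

    params: ParamSet
    scenarios: list[ScenarioSpec] = field(
        default_factory=lambda: list(DEFAULT_SCENARIOS))
    output_dir: Path = Path("results")
    log_level: str = "INFO"
    calibrate: bool = True


def _apply_override(raw: dict, path: str, value) -> None:
    keys = path.split(".")
    node = raw
    for k in keys[:-1]:
        if not isinstance(node, dict) or k not in node:
            raise ConfigError(f"override {path!r} does not reference an "
                              "existing parameter")
        node = node[k]
    leaf = keys[-1]
    if not isinstance(node, dict) or leaf not in node:
        raise ConfigError(f"override {path!r} does not reference an "
                          "existing parameter")
    node[leaf] = value


def load_and_validate_config(path: str | Path | None = None) -> RunConfig:
    """Parse, layer over defaults, materialize and validate a run config."""
    doc: dict = {}
    if path is not None:
        text = Path(path).read_text()
        doc = yaml.safe_load(text) or {}
        if not isinstance(doc, dict):
            raise ConfigError("config root must be a mapping")

    raw = copy.deepcopy(load_raw_defaults())
    for section in ("horizon", "anchors"):
        if section in doc:
            raw[section].update(doc[section])
    if "dt" in doc:
        raw["dt"] = doc["dt"]
    for path_, value in (doc.get("overrides") or {}).items():
        _apply_override(raw, str(path_), value)

    try:
        params = build_paramset(raw)
    except ParameterError as exc:
        raise ConfigError(str(exc)) from exc

    scenarios = list(DEFAULT_SCENARIOS)
    if "scenarios" in doc:
        try:
            scenarios = [ScenarioSpec(**s) for s in doc["scenarios"]]
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid scenario entry: {exc}") from exc

    return RunConfig(
        params=params,
        scenarios=scenarios,
        output_dir=Path(doc.get("output_dir", "results")),
        log_level=str(doc.get("log_level", "INFO")),
        calibrate=bool(doc.get("calibrate", True)),
    )


def summary_table(base: ProjectionResult,
                  increments: list[IncrementalResult]) -> pd.DataFrame:
    """Scenario summary shaped like the published intervention table.

    Counts in millions/thousands; costs in CAD billions (2 decimals in the
    CSV view is left to the writer -- full precision kept here).
    """
    rows = [{
        "intervention": "none", "effect_size": 0.0,
        "copd_total_2035_million": base.final("copd_total") / 1e6,
        "exacerbations_2035_million": base.final("exacerbations") / 1e6,
        "copd_deaths_2035_thousand": base.final("copd_deaths") / 1e3,
        "total_cost_billion": base.total_cost_discounted / 1e9,
        "total_qaly_lost_million": base.qaly_lost_discounted / 1e6,
        "incremental_cost_billion": 0.0,
        "incremental_qaly_million": 0.0,
        "monetary_benefit_billion": 0.0,
    }]
    for inc in increments:
        rows.append({
            "intervention": inc.scenario.split("_")[0],
            "effect_size": inc.effect_size,
            "copd_total_2035_million": inc.copd_total_final / 1e6,
            "exacerbations_2035_million": inc.exacerbations_final / 1e6,
            "copd_deaths_2035_thousand": inc.copd_deaths_final / 1e3,
            "total_cost_billion": inc.total_cost / 1e9,
            "total_qaly_lost_million": inc.total_qaly_lost / 1e6,
            "incremental_cost_billion": inc.delta_cost_saving / 1e9,
            "incremental_qaly_million": inc.delta_qaly_gain / 1e6,
            "monetary_benefit_billion": inc.monetary_benefit / 1e9,
        })
    return pd.DataFrame(rows)


def write_scenario_outputs(result: ProjectionResult, outdir: Path) -> None:
    """Per-scenario CSVs: annual ledger plus per-subgroup tables."""
    outdir.mkdir(parents=True, exist_ok=True)
    label = result.scenario
    cols = ["direct_cost", "indirect_cost", "total_cost", "qaly_lost",
            "direct_cost_disc", "indirect_cost_disc", "total_cost_disc",
            "qaly_lost_disc"]
    ledger = result.annual[cols].copy()
    cumulative = ledger.sum()
    cumulative.name = "cumulative"
    pd.concat([ledger, cumulative.to_frame().T]).to_csv(
        outdir / f"ledger_{label}.csv", index_label="year")
    for name, fname in (("population", f"population_{label}.csv"),
                        ("disease", f"disease_{label}.csv"),
                        ("events", f"events_{label}.csv")):
        if name in result.by_subgroup:
            result.by_subgroup[name].to_csv(outdir / fname, index=False)


def run_all(config: RunConfig, track_subgroups: bool = False
            ) -> tuple[dict[str, ProjectionResult], pd.DataFrame]:
    """Calibrate, run base plus scenarios, write every CSV, return results."""
    logging.basicConfig(level=config.log_level,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    ps = default_demography(ps=config.params) if config.calibrate \
        else config.params
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)

    results: dict[str, ProjectionResult] = {}
    base_spec = next((s for s in config.scenarios if s.intervention == "none"),
                     ScenarioSpec("none"))
    base = run_scenario(ps, base_spec, track_subgroups=track_subgroups)
    results[base.scenario] = base
    write_scenario_outputs(base, outdir)

    increments = []
    for spec in config.scenarios:
        if spec.intervention == "none":
            continue
        res = run_scenario(ps, spec, track_subgroups=track_subgroups)
        results[res.scenario] = res
        write_scenario_outputs(res, outdir)
        inc = compare_scenarios(base, res, ps.economics, spec.effect_size)
        increments.append(inc)
        inc_df = pd.DataFrame([inc.__dict__])
        inc_df.to_csv(outdir / f"incremental_{res.scenario}.csv", index=False)

    summary = summary_table(base, increments)
    summary.to_csv(outdir / "summary.csv", index=False,
                   float_format="%.6f")
    logger.info("wrote %d scenario result sets to %s", len(results), outdir)
    return results, summary


def run_tornado(config: RunConfig, relative_range: float = 0.25,
                parameters: list[str] | None = None) -> pd.DataFrame:
    """Calibrate, run the one-way sensitivity analysis, write tornado.csv."""
    ps = default_demography(ps=config.params) if config.calibrate \
        else config.params
    entries = one_way_sensitivity(ps, parameters, relative_range)
    df = pd.DataFrame([{
        "parameter_name": t.parameter_name,
        "low_value": t.low_value, "high_value": t.high_value,
        "cost_at_low": t.cost_at_low, "cost_at_high": t.cost_at_high,
        "span": t.span} for t in entries])
    config.output_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(config.output_dir / "tornado.csv", index=False)
    return df
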