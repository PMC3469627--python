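"""Hypothetical interventions and incremental scenario comparison.

Three zero-cost interventions, each a multiplicative reduction of an
annual rate, active from the start of the horizon:

* **I** (predisposition screen): reduces smoking initiation -- the
  never-to-current flow and the initiation-attributable current-smoker
  share of the cohort entering the 40-49 band -- by the effect size.
* **II** (progression-slowing drug): reduces both stage-progression
  hazards for all COPD patients.
* **III** (exacerbation prediction): reduces the exacerbation rate of
  every stage.

Incremental results use the savings-positive sign convention: a positive
``delta_cost_saving``/``delta_qaly_gain`` means the intervention helped.
"""

from __future__ import annotations

from dataclasses import dataclass

from .health_econ import net_monetary_benefit
from .model import ProjectionResult, simulate
from .params import EconParams, ParamSet

INTERVENTIONS = ("none", "I", "II", "III")

#: long-form aliases accepted in configs
_ALIASES = {
    "none": "none",
    "i": "I", "i_predisposition_screen": "I",
    "ii": "II", "ii_progression_drug": "II",
    "iii": "III", "iii_exacerbation_test": "III",
}


@dataclass(frozen=True)
class ScenarioSpec:
    """An intervention identifier with its effect size (rate reduction)."""

    intervention: str = "none"
    effect_size: float = 0.0
    start_year: int = 2011

    def __post_init__(self):
        key = _ALIASES.get(str(self.intervention).lower())
        if key is None:
            raise ValueError(f"unknown intervention {self.intervention!r}; "
                             f"expected one of {INTERVENTIONS}")
        object.__setattr__(self, "intervention", key)
        if key != "none" and not 0.0 < self.effect_size < 1.0:
            raise ValueError("effect_size must lie in (0, 1) for an active "
                             "intervention")

    @property
    def label(self) -> str:
        if self.intervention == "none":
            return "none"
        return f"{self.intervention}_{int(round(self.effect_size * 100))}pct"


@dataclass
class IncrementalResult:
    """Scenario outcomes and base-minus-scenario increments."""

    scenario: str
    effect_size: float
    copd_total_final: float
    exacerbations_final: float
    copd_deaths_final: float
    total_cost: float                  # cumulative discounted, scenario
    total_qaly_lost: float             # cumulative discounted, scenario
    delta_cost_saving: float
    delta_qaly_gain: float
    delta_copd_count: float
    delta_exacerbations: float
    delta_copd_deaths: float
    monetary_benefit: float


def apply_intervention(params: ParamSet, spec: ScenarioSpec) -> ParamSet:
    """Return a copy of ``params`` with the intervention's rate scaling."""
    ps = params.copy()
    e = spec.effect_size
    if spec.intervention == "none":
        return ps
    if spec.intervention == "I":
        ps.demography.initiation_multiplier *= (1.0 - e)
    elif spec.intervention == "II":
        # hazard x (1-e)  <=>  mean progression time / (1-e)
        ps.disease.progression_times = ps.disease.progression_times / (1.0 - e)
    elif spec.intervention == "III":
        ps.events.exacerbation_rate = ps.events.exacerbation_rate * (1.0 - e)
    return ps


def run_scenario(params: ParamSet, spec: ScenarioSpec,
                 track_subgroups: bool = False) -> ProjectionResult:
    """Full projection under the modified parameter set."""
    return simulate(apply_intervention(params, spec), scenario=spec.label,
                    track_subgroups=track_subgroups)


def compare_scenarios(base: ProjectionResult, scenario: ProjectionResult,
                      ec: EconParams, effect_size: float = 0.0
                      ) -> IncrementalResult:
    """Base-minus-scenario increments and the net monetary benefit."""
    if list(base.annual.index) != list(scenario.annual.index):
        raise ValueError("scenario horizons differ; cannot compare")
    d_cost = base.total_cost_discounted - scenario.total_cost_discounted
    d_qaly = base.qaly_lost_discounted - scenario.qaly_lost_discounted
    return IncrementalResult(
        scenario=scenario.scenario,
        effect_size=effect_size,
        copd_total_final=scenario.final("copd_total"),
        exacerbations_final=scenario.final("exacerbations"),
        copd_deaths_final=scenario.final("copd_deaths"),
        total_cost=scenario.total_cost_discounted,
        total_qaly_lost=scenario.qaly_lost_discounted,
        delta_cost_saving=d_cost,
        delta_qaly_gain=d_qaly,
        delta_copd_count=scenario.final("copd_total")
        - base.final("copd_total"),
        delta_exacerbations=base.final("exacerbations")
        - scenario.final("exacerbations"),
        delta_copd_deaths=base.final("copd_deaths")
        - scenario.final("copd_deaths"),
        monetary_benefit=net_monetary_benefit(d_cost, d_qaly, ec),
    )
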