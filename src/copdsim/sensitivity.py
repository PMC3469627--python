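"""One-way (tornado) sensitivity analysis on cumulative discounted cost.

Each named parameter is perturbed to (1 - r) and (1 + r) times its default
while everything else stays fixed, the full projection is re-run, and
parameters are ranked by the induced span in the cumulative discounted
societal cost.  Only the ranking is meaningful: the perturbation range is
a convention (default +/-25%), not an estimate of parameter uncertainty.

The registry covers the parameters called out in the original analysis:
exacerbation rates, population growth (the entry and net-migration
inflows), the relative risk of COPD in previous and in current smokers
(multipliers on those groups' COPD stage prevalences, renormalized),
progression rates, and spirometry uptake.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import simulate
from .params import ParamSet


def _scale_stage_prevalence(ps: ParamSet, smoke_idx: int, f: float) -> None:
    dist = ps.disease.stage_distribution.copy()
    dist[:, :, smoke_idx, 1:] *= f
    dist[:, :, smoke_idx, 0] = 1.0 - dist[:, :, smoke_idx, 1:].sum(axis=-1)
    if np.any(dist < 0):
        raise ValueError("COPD relative-risk perturbation exceeds 100% "
                         "prevalence")
    ps.disease.stage_distribution = dist


def _set_exacerbation(ps, f):
    ps.events.exacerbation_rate = ps.events.exacerbation_rate * f


def _set_population_growth(ps, f):
    ps.demography.entry_rate_per_sex = ps.demography.entry_rate_per_sex * f
    ps.demography.net_migration_rate = ps.demography.net_migration_rate * f


def _set_progression(ps, f):
    ps.disease.progression_times = ps.disease.progression_times / f


def _set_uptake(ps, f):
    ps.disease.spirometry_uptake = min(ps.disease.spirometry_uptake * f, 1.0)


def _set_prev_smoker_rr(ps, f):
    _scale_stage_prevalence(ps, 1, f)


def _set_current_smoker_rr(ps, f):
    _scale_stage_prevalence(ps, 0, f)


def _set_minor_episode_cost(ps, f):
    ps.economics.direct_minor_episode *= f
    ps.economics.indirect_minor_episode = \
        ps.economics.indirect_minor_episode * f


def _set_major_episode_cost(ps, f):
    ps.economics.direct_major_episode *= f
    ps.economics.indirect_major_episode = \
        ps.economics.indirect_major_episode * f


PARAMETER_REGISTRY = {
    "exacerbation_rate": _set_exacerbation,
    "population_growth": _set_population_growth,
    "previous_smoker_copd_rr": _set_prev_smoker_rr,
    "current_smoker_copd_rr": _set_current_smoker_rr,
    "progression_rate": _set_progression,
    "spirometry_uptake": _set_uptake,
    "minor_episode_cost": _set_minor_episode_cost,
    "major_episode_cost": _set_major_episode_cost,
}

DEFAULT_PARAMETERS = ("exacerbation_rate", "population_growth",
                      "previous_smoker_copd_rr", "current_smoker_copd_rr",
                      "progression_rate", "spirometry_uptake")


@dataclass
class TornadoEntry:
    """One bar of the tornado: outcome at the low and high perturbation."""

    parameter_name: str
    low_value: float             # multiplier applied (1 - r)
    high_value: float            # multiplier applied (1 + r)
    cost_at_low: float
    cost_at_high: float

    @property
    def span(self) -> float:
        return abs(self.cost_at_high - self.cost_at_low)


def one_way_sensitivity(ps: ParamSet, parameters: list[str] | None = None,
                        relative_range: float = 0.25) -> list[TornadoEntry]:
    """Tornado entries sorted by descending span; deterministic."""
    parameters = list(parameters or DEFAULT_PARAMETERS)
    unknown = [p for p in parameters if p not in PARAMETER_REGISTRY]
    if unknown:
        raise KeyError(f"unknown sensitivity parameter(s): "
                       f"{', '.join(unknown)}; known: "
                       f"{', '.join(sorted(PARAMETER_REGISTRY))}")
    entries = []
    for name in parameters:
        costs = {}
        for f in (1.0 - relative_range, 1.0 + relative_range):
            trial = ps.copy()
            PARAMETER_REGISTRY[name](trial, f)
            costs[f] = simulate(trial, scenario=f"{name}@{f:.2f}"
                                ).total_cost_discounted
        lo, hi = 1.0 - relative_range, 1.0 + relative_range
        entries.append(TornadoEntry(parameter_name=name, low_value=lo,
                                    high_value=hi, cost_at_low=costs[lo],
                                    cost_at_high=costs[hi]))
    entries.sort(key=lambda t: t.span, reverse=True)
    return entries
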