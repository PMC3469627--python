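"""The full projection: demography x natural history x events x economics.

One run advances the 2011 state to 2035 with explicit Euler steps
(default dt = 0.25 years).  Within each sub-step the operation order is
fixed for reproducibility: event tally and economic accrual on the
start-of-step stocks, then deaths, then stage progression, then the
demographic flows, then the mild-incidence top-up that pins each
subgroup's mild prevalence to its published value.

Stocks reported for a calendar year are the start-of-year stocks (so the
2011 row is the initial state); flows, costs and QALYs reported for a
year are the amounts accrued during it, discounted with that year's
integer-exponent factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import events as ev
from . import health_econ as he
from . import natural_history as nh
from .params import AGE_BANDS, ParamSet, SEXES, SMOKING

#: per-compartment split of the entering cohort (non-COPD diagnosis cascade)
_ENTRY_COMPARTMENTS = ("tn", "fp", "untested")


@dataclass
class ProjectionResult:
    """Per-year ledgers of counts, events, costs and QALYs for one scenario."""

    scenario: str
    annual: pd.DataFrame                    # indexed by calendar year
    by_subgroup: dict[str, pd.DataFrame] = field(default_factory=dict)

    # -- cumulative horizon totals ------------------------------------
    def cumulative(self, column: str) -> float:
        return float(self.annual[column].sum())

    @property
    def total_cost_discounted(self) -> float:
        return self.cumulative("total_cost_disc")

    @property
    def total_cost_undiscounted(self) -> float:
        return self.cumulative("total_cost")

    @property
    def qaly_lost_discounted(self) -> float:
        return self.cumulative("qaly_lost_disc")

    @property
    def qaly_lost_undiscounted(self) -> float:
        return self.cumulative("qaly_lost")

    def final(self, column: str) -> float:
        return float(self.annual[column].iloc[-1])


def simulate(ps: ParamSet, scenario: str = "none",
             track_subgroups: bool = False) -> ProjectionResult:
    """Run the deterministic projection over the configured horizon."""
    ps.require_valid()
    dp, dis, epar = ps.demography, ps.disease, ps.events
    up, ec = ps.utilities, ps.economics
    steps = round(1.0 / ps.dt)
    years = list(range(ps.year_start, ps.year_end + 1))

    state = nh.initial_state(ps)
    # mortality is applied explicitly (events module) before the other
    # demographic flows, so the compartment stepper runs with it zeroed
    import copy as _copy
    dp_flows = _copy.deepcopy(dp)
    dp_flows.background_mortality = np.zeros_like(dp.background_mortality)
    annuities = he.death_qaly_annuities(up, ec, ps.year_start, ps.year_end,
                                        dp.aging_rates)
    nc_frac = nh.no_copd_cascade_fractions(dis)       # (SEX, SMOKE, 3)
    entry_split = {name: nc_frac[:, :, j]
                   for j, name in enumerate(_ENTRY_COMPARTMENTS)}

    rows = []
    subgroup_frames = {"population": [], "disease": [], "events": []}
    for j, year in enumerate(years):
        df_year = float(he.discount_factor(year, ec))
        start_state = state.copy()
        acc = {k: 0.0 for k in
               ("minor", "major", "copd_deaths", "background_deaths",
                "direct_cost", "indirect_cost", "qaly_chronic",
                "qaly_exacerbation", "qaly_death", "qaly_death_disc",
                "mild_incidence", "entries", "migration")}
        year_minor = np.zeros_like(state.mild())
        year_major = np.zeros_like(state.mild())
        year_minor_stage = None
        for _ in range(steps):
            tally = ev.tally_events(state, epar, dp.background_mortality,
                                    ps.dt)
            cost = he.accrue_costs(state, tally, ec, ps.dt)
            qaly = he.accrue_qalys(state, tally, up, ps.dt,
                                   death_annuity=annuities, year_index=j,
                                   ref_discount=df_year)
            acc["minor"] += float(tally.minor.sum())
            acc["major"] += float(tally.major.sum())
            acc["copd_deaths"] += float(tally.copd_deaths.sum())
            acc["background_deaths"] += float(tally.background_deaths.sum())
            acc["direct_cost"] += cost.direct_cost
            acc["indirect_cost"] += cost.indirect_cost
            acc["qaly_chronic"] += qaly.qaly_chronic
            acc["qaly_exacerbation"] += qaly.qaly_exacerbation
            acc["qaly_death"] += qaly.qaly_death
            acc["qaly_death_disc"] += qaly.qaly_death_discounted
            if year_minor_stage is None:
                year_minor_stage = tally.minor.copy()
                year_major_stage = tally.major.copy()
                year_deaths_stage = tally.copd_deaths.copy()
                year_bg = tally.background_deaths.copy()
            else:
                year_minor_stage += tally.minor
                year_major_stage += tally.major
                year_deaths_stage += tally.copd_deaths
                year_bg += tally.background_deaths

            state = ev.apply_copd_deaths(state, tally)
            state = ev.apply_background_deaths(state, dp.background_mortality,
                                               ps.dt)
            state = nh.step_disease(state, dis, ps.dt)
            arrays, flows = step_demography(state, dp_flows, ps.dt,
                                            entry_split)
            state = nh.DiseaseState(**arrays)
            acc["entries"] += flows.entries
            acc["migration"] += flows.migration
            inc = nh.mild_incidence_to_hold_prevalence(state, dis,
                                                       warn=False)
            acc["mild_incidence"] += float(inc.sum())
            state = nh.apply_mild_incidence(state, inc, dis)

        mild = start_state.mild()
        pop = start_state.population()
        row = {
            "year": year,
            "population": float(pop.sum()),
            "pop_70plus": float(pop[:, 3, :].sum()),
            "copd_total": start_state.copd_total(),
            "mild": float(mild.sum()),
            "moderate": float(start_state.moderate.sum()),
            "severe": float(start_state.severe.sum()),
            "mild_tp": float(start_state.mild_tp.sum()),
            "mild_fn": float(start_state.mild_fn.sum()),
            "mild_ud": float(start_state.mild_ud.sum()),
            "fp": float(start_state.fp.sum()),
            "copd_current_smokers": float(
                start_state.copd_by_stage()[:, :, :, 0].sum()),
            "mild_men": float(mild[0].sum()),
            "pop_men": float(pop[0].sum()),
            "exacerbations": acc["minor"] + acc["major"],
            "minor": acc["minor"],
            "major": acc["major"],
            "copd_deaths": acc["copd_deaths"],
            "background_deaths": acc["background_deaths"],
            "mild_incidence": acc["mild_incidence"],
            "entries": acc["entries"],
            "net_migration": acc["migration"],
            "direct_cost": acc["direct_cost"],
            "indirect_cost": acc["indirect_cost"],
            "total_cost": acc["direct_cost"] + acc["indirect_cost"],
            "qaly_lost": (acc["qaly_chronic"] + acc["qaly_exacerbation"]
                          + acc["qaly_death"]),
            "qaly_chronic": acc["qaly_chronic"],
            "qaly_exacerbation": acc["qaly_exacerbation"],
            "qaly_death": acc["qaly_death"],
        }
        row["direct_cost_disc"] = row["direct_cost"] * df_year
        row["indirect_cost_disc"] = row["indirect_cost"] * df_year
        row["total_cost_disc"] = row["total_cost"] * df_year
        row["qaly_lost_disc"] = ((acc["qaly_chronic"]
                                  + acc["qaly_exacerbation"]) * df_year
                                 + acc["qaly_death_disc"])
        rows.append(row)

        if track_subgroups:
            _append_subgroup_rows(subgroup_frames, year, start_state,
                                  year_minor_stage, year_major_stage,
                                  year_deaths_stage, year_bg)

    annual = pd.DataFrame(rows).set_index("year")
    by_subgroup = {}
    if track_subgroups:
        by_subgroup = {k: pd.DataFrame(v) for k, v in subgroup_frames.items()}
    return ProjectionResult(scenario=scenario, annual=annual,
                            by_subgroup=by_subgroup)


def step_demography(state: nh.DiseaseState, dp, dt, entry_split):
    """Demographic flows applied to every disease compartment."""
    from .demography import step_compartments
    return step_compartments(state.arrays(), dp, dt, entry_split=entry_split)


def _append_subgroup_rows(frames, year, state, minor, major, copd_deaths, bg):
    pop = state.population()
    for i, sex in enumerate(SEXES):
        for a, band in enumerate(AGE_BANDS):
            for k, smoke in enumerate(SMOKING):
                frames["population"].append({
                    "year": year, "sex": sex, "age_band": band,
                    "smoking": smoke, "persons": float(pop[i, a, k])})
                for name, arr in state.arrays().items():
                    frames["disease"].append({
                        "year": year, "sex": sex, "age_band": band,
                        "smoking": smoke, "compartment": name,
                        "persons": float(arr[i, a, k])})
                for s, stage in enumerate(("mild", "moderate", "severe")):
                    frames["events"].append({
                        "year": year, "sex": sex, "age_band": band,
                        "smoking": smoke, "stage": stage,
                        "minor": float(minor[s, i, a, k]),
                        "major": float(major[s, i, a, k]),
                        "copd_deaths": float(copd_deaths[s, i, a, k]),
                        "background_deaths": float(bg[i, a, k]) if s == 0
                        else 0.0})
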