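"""Costs, QALYs, discounting and net monetary benefit.

Cost accounting follows the diagnosis cascade: undiagnosed and
false-negative mild patients generate no maintenance costs, while true
positives, false positives (costed as mild), and all moderate/severe
patients do; exacerbation episode costs accrue for every episode
regardless of diagnosis status.  Indirect costs use the published
per-unit values (the 20/33/45% shares of total costs they imply are a
consistency check, not an input).

QALY losses are areas between the age-specific EQ-5D reference curve and
the patient's utility: a chronic decrement per person-year at each stage
(clamped at zero where the reference dips below the stage utility, as it
does for mild disease at 70+), an episode decrement for the duration of
each exacerbation, and, for every COPD death, the full reference-utility
stream from death to the end of the horizon, with the decedent aged
forward along the bands.  False positives lose no utility.

All amounts are 2011 CAD, discounted at a fixed annual rate to 2011.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .events import EventTally
from .natural_history import DiseaseState
from .params import EconParams, EventParams, UtilityParams, N_AGE

STAGE_IDX = {"mild": 0, "moderate": 1, "severe": 2}


def annual_cost_per_patient(stage: str | int, ep: EventParams,
                            ec: EconParams, component: str = "direct"
                            ) -> float:
    """Expected annual cost per (diagnosed) patient at a stage.

    Maintenance plus the exacerbation rate times the minor/major-weighted
    episode costs; this identity reproduces the published per-patient
    totals from their primitive inputs.
    """
    s = STAGE_IDX[stage] if isinstance(stage, str) else int(stage)
    if component == "direct":
        minor_cost = ec.direct_minor_episode
        major_cost = ec.direct_major_episode
        maint = ec.direct_maintenance[s]
    elif component == "indirect":
        minor_cost = ec.indirect_minor_episode[s]
        major_cost = ec.indirect_major_episode[s]
        maint = ec.indirect_maintenance[s]
    else:
        raise ValueError(f"unknown cost component {component!r}")
    episode = (ep.minor_fraction[s] * minor_cost
               + ep.major_fraction[s] * major_cost)
    return float(maint + ep.exacerbation_rate[s] * episode)


def discount_factor(year, ec: EconParams):
    """Present-value factor for amounts accrued in a calendar year."""
    year = np.asarray(year)
    if np.any(year < ec.base_year):
        raise ValueError("cannot discount to a year before the base year")
    return (1.0 + ec.discount_rate) ** -(year - ec.base_year)


def discount(amount, year, ec: EconParams):
    """Discount an amount accrued in ``year`` to the base year."""
    return amount * discount_factor(year, ec)


def net_monetary_benefit(delta_cost_saving: float, delta_qaly_gain: float,
                         ec: EconParams) -> float:
    """Willingness-to-pay times QALYs gained, plus cost savings."""
    return ec.wtp_per_qaly * delta_qaly_gain + delta_cost_saving


@dataclass
class LedgerIncrement:
    """Undiscounted cost and QALY amounts accrued over one step."""

    direct_cost: float = 0.0
    indirect_cost: float = 0.0
    qaly_chronic: float = 0.0
    qaly_exacerbation: float = 0.0
    qaly_death: float = 0.0
    qaly_death_discounted: float = 0.0   # death annuities discount internally

    @property
    def total_cost(self) -> float:
        return self.direct_cost + self.indirect_cost

    @property
    def qaly_lost(self) -> float:
        return self.qaly_chronic + self.qaly_exacerbation + self.qaly_death


def accrue_costs(state: DiseaseState, tally: EventTally, ec: EconParams,
                 dt: float) -> LedgerIncrement:
    """Maintenance and episode costs over one step, undiscounted."""
    maint_pop = np.stack([state.mild_tp + state.fp,   # FP costed at mild stage
                          state.moderate, state.severe])
    persons = maint_pop.sum(axis=(1, 2, 3))
    minor = tally.minor.sum(axis=(1, 2, 3))
    major = tally.major.sum(axis=(1, 2, 3))
    direct = float((persons * ec.direct_maintenance).sum() * dt
                   + minor.sum() * ec.direct_minor_episode
                   + major.sum() * ec.direct_major_episode)
    indirect = float((persons * ec.indirect_maintenance).sum() * dt
                     + (minor * ec.indirect_minor_episode).sum()
                     + (major * ec.indirect_major_episode).sum())
    return LedgerIncrement(direct_cost=direct, indirect_cost=indirect)


def death_qaly_annuities(up: UtilityParams, ec: EconParams, year_start: int,
                         year_end: int, aging_rates: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Remaining reference-utility QALYs per (age band, calendar year).

    Backward recursion over the horizon: a decedent's counterfactual self
    accrues the band's reference utility each year and ages to the next
    band at the band transfer rate.  Returns ``(undiscounted, discounted)``
    arrays of shape (AGE, n_years); the discounted variant applies the
    calendar-year discount factor inside the annuity.
    """
    n = year_end - year_start + 1
    undisc = np.zeros((N_AGE, n + 1))
    disc = np.zeros((N_AGE, n + 1))
    for j in range(n - 1, -1, -1):
        df = discount_factor(year_start + j, ec)
        for b in range(N_AGE):
            a = aging_rates[b]
            nxt = min(b + 1, N_AGE - 1)
            undisc[b, j] = (up.reference_by_age[b]
                            + (1.0 - a) * undisc[b, j + 1]
                            + a * undisc[nxt, j + 1])
            disc[b, j] = (up.reference_by_age[b] * df
                          + (1.0 - a) * disc[b, j + 1]
                          + a * disc[nxt, j + 1])
    return undisc[:, :n], disc[:, :n]


def accrue_qalys(state: DiseaseState, tally: EventTally, up: UtilityParams,
                 dt: float,
                 death_annuity: tuple[np.ndarray, np.ndarray] | None = None,
                 year_index: int | None = None,
                 ref_discount: float = 1.0) -> LedgerIncrement:
    """QALY losses over one step: chronic, exacerbation, death components.

    ``death_annuity``/``year_index`` attach horizon-bounded death losses at
    the year of death (both omitted: deaths contribute nothing, as in
    single-step unit analyses).  ``ref_discount`` is the calendar-year
    discount factor used for the mid-year correction of death losses.
    """
    ref = up.reference_by_age[None, :, None]              # (1, AGE, 1)
    stocks = state.copd_by_stage()                        # (3, SEX, AGE, SMOKE)
    chronic_dec = np.maximum(ref - up.chronic_by_stage[:, None, None, None],
                             0.0)
    chronic = float((stocks * chronic_dec).sum() * dt)

    minor_dec = np.maximum(up.chronic_by_stage - up.minor_exac_by_stage, 0.0)
    major_dec = np.maximum(up.chronic_by_stage - up.major_exac_by_stage, 0.0)
    exac = float(
        (tally.minor.sum(axis=(1, 2, 3)) * minor_dec).sum()
        * up.minor_episode_duration
        + (tally.major.sum(axis=(1, 2, 3)) * major_dec).sum()
        * up.major_episode_duration)

    death = death_disc = 0.0
    if death_annuity is not None and year_index is not None:
        undisc_tab, disc_tab = death_annuity
        deaths_by_band = tally.copd_deaths.sum(axis=(0, 1, 3))    # (AGE,)
        # deaths occur mid-year on average: subtract half a year of reference
        half = 0.5 * up.reference_by_age
        death = float((deaths_by_band
                       * (undisc_tab[:, year_index] - half)).sum())
        death_disc = float((deaths_by_band
                            * (disc_tab[:, year_index]
                               - half * ref_discount)).sum())
    return LedgerIncrement(qaly_chronic=chronic, qaly_exacerbation=exac,
                           qaly_death=death, qaly_death_discounted=death_disc)
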