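"""Exacerbation episodes and deaths.

Episode counts are deterministic expected values: each stage stock
generates ``rate x dt`` episodes per person, split into minor and major
with the published stage-specific fractions.  Every COPD patient is at
exacerbation risk regardless of diagnosis status (UD and FN included).
All COPD-attributable deaths ride on major exacerbations with a fixed
probability of death per major episode; background mortality applies
uniformly to every compartment of a subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .natural_history import DiseaseState
from .params import EventParams


@dataclass
class EventTally:
    """Expected event counts per subgroup and stage over one step.

    ``minor``/``major``/``copd_deaths`` have shape (3, SEX, AGE, SMOKE)
    indexed by stage; ``background_deaths`` is summed over compartments,
    shape (SEX, AGE, SMOKE).
    """

    minor: np.ndarray
    major: np.ndarray
    copd_deaths: np.ndarray
    background_deaths: np.ndarray

    @property
    def episodes(self) -> np.ndarray:
        return self.minor + self.major


def tally_events(state: DiseaseState, ep: EventParams,
                 background_mortality: np.ndarray, dt: float) -> EventTally:
    """Expected exacerbations and deaths over a step of ``dt`` years."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    stocks = state.copd_by_stage()                       # (3, SEX, AGE, SMOKE)
    episodes = stocks * ep.exacerbation_rate[:, None, None, None] * dt
    minor = episodes * ep.minor_fraction[:, None, None, None]
    major = episodes * ep.major_fraction[:, None, None, None]
    copd_deaths = major * ep.death_prob_per_major
    background = state.population() * background_mortality * dt
    return EventTally(minor=minor, major=major, copd_deaths=copd_deaths,
                      background_deaths=background)


def apply_copd_deaths(state: DiseaseState, tally: EventTally) -> DiseaseState:
    """Remove exacerbation-attributable deaths from the stage stocks.

    Mild deaths are shared across TP/FN/UD in proportion to their stocks.
    """
    new = state.copy()
    mild = state.mild()
    with np.errstate(invalid="ignore", divide="ignore"):
        safe = np.where(mild > 0, mild, 1.0)
        for name in ("mild_tp", "mild_fn", "mild_ud"):
            share = np.where(mild > 0, getattr(state, name) / safe, 0.0)
            arr = getattr(new, name)
            arr -= tally.copd_deaths[0] * share
    new.moderate -= tally.copd_deaths[1]
    new.severe -= tally.copd_deaths[2]
    return new


def apply_background_deaths(state: DiseaseState,
                            background_mortality: np.ndarray,
                            dt: float) -> DiseaseState:
    """Thin every compartment by the subgroup background mortality."""
    new = state.copy()
    surv = 1.0 - background_mortality * dt
    if np.any(surv < 0):
        raise ValueError("dt too large: background mortality outflow exceeds "
                         "a stock; use a smaller dt")
    for name, arr in new.arrays().items():
        setattr(new, name, arr * surv)
    return new
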