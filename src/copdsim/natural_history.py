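"""COPD disease states and the imperfect-diagnosis cascade.

Disease stocks are carried per (sex, age band, smoking status) subgroup in
eight compartments:

* no COPD: true negative (``tn``), false positive (``fp``), untested
  (``untested`` = asymptomatic plus symptomatic people who never had
  spirometry);
* mild COPD: true positive (``mild_tp``), false negative (``mild_fn``),
  undiagnosed (``mild_ud`` = asymptomatic mild plus symptomatic mild without
  spirometry);
* ``moderate`` and ``severe`` COPD, which carry no UD/FN sub-stocks --
  progression is assumed to surface the diagnosis, so everyone at those
  stages is correctly diagnosed.

Subgroup mild prevalence is held at its published value: each step, mild
incidence tops the mild stocks back up to ``stage_distribution(mild)`` times
the subgroup population, so incidence tracks population change plus the
progression and death outflows.  Moderate and severe stocks are fully
dynamic, fed only by progression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np

from .params import DiseaseParams, N_AGE, N_SEX, N_SMOKE, ParamSet

logger = logging.getLogger(__name__)

COMPARTMENTS = ("tn", "fp", "untested", "mild_tp", "mild_fn", "mild_ud",
                "moderate", "severe")


@dataclass
class DiseaseState:
    """Person counts per subgroup and compartment, each array (2, 4, 3)."""

    tn: np.ndarray
    fp: np.ndarray
    untested: np.ndarray
    mild_tp: np.ndarray
    mild_fn: np.ndarray
    mild_ud: np.ndarray
    moderate: np.ndarray
    severe: np.ndarray

    @classmethod
    def zeros(cls) -> "DiseaseState":
        return cls(**{name: np.zeros((N_SEX, N_AGE, N_SMOKE))
                      for name in COMPARTMENTS})

    def copy(self) -> "DiseaseState":
        return DiseaseState(**{f.name: getattr(self, f.name).copy()
                               for f in fields(self)})

    def arrays(self) -> dict[str, np.ndarray]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def population(self) -> np.ndarray:
        """(SEX, AGE, SMOKE) total persons."""
        return sum(getattr(self, name) for name in COMPARTMENTS)

    def mild(self) -> np.ndarray:
        return self.mild_tp + self.mild_fn + self.mild_ud

    def copd_by_stage(self) -> np.ndarray:
        """(3, SEX, AGE, SMOKE): mild, moderate, severe stocks."""
        return np.stack([self.mild(), self.moderate, self.severe])

    def copd_total(self) -> float:
        return float(self.copd_by_stage().sum())

    def non_negative(self, tol: float = -1e-6) -> bool:
        return all(getattr(self, name).min() >= tol for name in COMPARTMENTS)


@dataclass
class DiagnosisPartition:
    """Outcome of the symptom/spirometry cascade on a cohort."""

    tp: np.ndarray | float
    fn: np.ndarray | float
    ud: np.ndarray | float
    tn: np.ndarray | float
    fp: np.ndarray | float


def classify_diagnosis(mild_symptomatic, mild_asymptomatic,
                       no_copd_symptomatic, p: DiseaseParams
                       ) -> DiagnosisPartition:
    """Partition a cohort through spirometry uptake, sensitivity, specificity.

    Symptomatic mild cases who undergo spirometry (uptake) test true
    positive with the test's sensitivity, else false negative; symptomatic
    mild cases without spirometry and all asymptomatic mild cases are
    undiagnosed.  Symptomatic people without COPD who undergo spirometry
    test true negative with the specificity, else false positive.
    """
    mild_symptomatic = np.asarray(mild_symptomatic, dtype=float)
    mild_asymptomatic = np.asarray(mild_asymptomatic, dtype=float)
    no_copd_symptomatic = np.asarray(no_copd_symptomatic, dtype=float)
    if (np.any(mild_symptomatic < 0) or np.any(mild_asymptomatic < 0)
            or np.any(no_copd_symptomatic < 0)):
        raise ValueError("cohort sizes must be non-negative")
    u = p.spirometry_uptake
    se = p.spirometry_sensitivity
    sp = p.spirometry_specificity
    return DiagnosisPartition(
        tp=mild_symptomatic * u * se,
        fn=mild_symptomatic * u * (1.0 - se),
        ud=mild_symptomatic * (1.0 - u) + mild_asymptomatic,
        tn=no_copd_symptomatic * u * sp,
        fp=no_copd_symptomatic * u * (1.0 - sp),
    )


def mild_cascade_fractions(p: DiseaseParams) -> np.ndarray:
    """(SEX, SMOKE, 3) fractions of a mild cohort landing in TP/FN/UD."""
    s = p.symptom_prevalence[..., 1]          # symptomatic fraction with COPD
    part = classify_diagnosis(s, 1.0 - s, np.zeros_like(s), p)
    return np.stack([part.tp, part.fn, part.ud], axis=-1)


def no_copd_cascade_fractions(p: DiseaseParams) -> np.ndarray:
    """(SEX, SMOKE, 3) fractions of a non-COPD cohort landing in TN/FP/untested."""
    s = p.symptom_prevalence[..., 0]
    part = classify_diagnosis(np.zeros_like(s), np.zeros_like(s), s, p)
    untested = 1.0 - s * p.spirometry_uptake
    return np.stack([part.tn, part.fp, untested], axis=-1)


def initial_state(ps: ParamSet) -> DiseaseState:
    """2011 stocks: stage distribution, then symptoms, then diagnosis.

    Initial moderate and severe cases are all treated as diagnosed (TP).
    """
    pop = ps.demography.initial_population()       # (SEX, AGE, SMOKE)
    dist = ps.disease.stage_distribution
    state = DiseaseState.zeros()

    non_copd = pop * dist[..., 0]
    mild = pop * dist[..., 1]
    state.moderate = pop * dist[..., 2]
    state.severe = pop * dist[..., 3]

    mild_frac = mild_cascade_fractions(ps.disease)       # (SEX, SMOKE, 3)
    state.mild_tp = mild * mild_frac[:, None, :, 0]
    state.mild_fn = mild * mild_frac[:, None, :, 1]
    state.mild_ud = mild * mild_frac[:, None, :, 2]

    nc_frac = no_copd_cascade_fractions(ps.disease)
    state.tn = non_copd * nc_frac[:, None, :, 0]
    state.fp = non_copd * nc_frac[:, None, :, 1]
    state.untested = non_copd * nc_frac[:, None, :, 2]
    return state


def step_disease(state: DiseaseState, p: DiseaseParams, dt: float
                 ) -> DiseaseState:
    """Advance stage progression by one Euler step of length ``dt`` years.

    Mild to moderate and moderate to severe flows run at the reciprocal of
    the mean progression times, identically across TP/FN/UD mild stocks;
    progressing UD and FN cases surface as diagnosed.  Severe is absorbing
    (deaths are handled by the events module).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    h = p.progression_hazards()                       # (SEX, SMOKE, 2)
    h1 = h[:, None, :, 0] * dt                        # mild -> moderate
    h2 = h[:, None, :, 1] * dt                        # moderate -> severe
    if np.any(h1 > 1.0) or np.any(h2 > 1.0):
        raise ValueError("dt too large: a progression outflow exceeds its "
                         "stock; use a smaller dt")
    new = state.copy()
    out_tp = state.mild_tp * h1
    out_fn = state.mild_fn * h1
    out_ud = state.mild_ud * h1
    out_mod = state.moderate * h2
    new.mild_tp -= out_tp
    new.mild_fn -= out_fn
    new.mild_ud -= out_ud
    new.moderate += out_tp + out_fn + out_ud - out_mod
    new.severe += out_mod
    return new


def mild_incidence_to_hold_prevalence(state: DiseaseState, p: DiseaseParams,
                                      warn: bool = True) -> np.ndarray:
    """(SEX, AGE, SMOKE) incident mild cases restoring the target prevalence.

    The target is ``stage_distribution(mild)`` times the current subgroup
    population; the shortfall after demography, progression and deaths is
    the incidence, floored at zero (with a log warning, suppressible for
    callers that aggregate their own) if the mild stocks ever overshoot
    the target.  Overshoots arise transiently when smoking cessation moves
    mild cases from a high-prevalence into a low-prevalence subgroup; they
    are absorbed by that subgroup's outflows within subsequent steps.
    """
    target = p.mild_prevalence()
    if np.any(target > 1.0):
        raise ValueError("target mild prevalence above 1")
    need = target * state.population() - state.mild()
    if warn and np.any(need < -1e-6 * np.maximum(state.population(), 1.0)):
        logger.warning("mild stocks exceed target prevalence in %d subgroups; "
                       "incidence floored at zero", int(np.sum(need < 0)))
    return np.maximum(need, 0.0)


def incidence_balance(pop_change, mild_outflows, target_prevalence):
    """Closed-form incidence keeping mild prevalence at its target.

    With a population change of ``pop_change`` persons and ``mild_outflows``
    mild cases lost to progression or death, the incidence that leaves the
    prevalence unchanged is ``target_prevalence * pop_change +
    mild_outflows``, floored at zero.  This is the balance the stateful
    top-up in :func:`mild_incidence_to_hold_prevalence` enforces.
    """
    target_prevalence = np.asarray(target_prevalence, dtype=float)
    if np.any(target_prevalence > 1.0):
        raise ValueError("target mild prevalence above 1")
    return np.maximum(target_prevalence * np.asarray(pop_change, dtype=float)
                      + np.asarray(mild_outflows, dtype=float), 0.0)


def apply_mild_incidence(state: DiseaseState, incidence: np.ndarray,
                         p: DiseaseParams) -> DiseaseState:
    """Move incident mild cases out of the non-COPD pool, via the cascade.

    New cases are drawn proportionally from the TN and untested stocks
    (false positives are left alone) and partitioned into TP/FN/UD with the
    subgroup's symptomatic-mild cascade fractions.
    """
    new = state.copy()
    pool = state.tn + state.untested
    draw = np.minimum(incidence, pool)
    with np.errstate(invalid="ignore", divide="ignore"):
        w_tn = np.where(pool > 0, state.tn / np.where(pool > 0, pool, 1.0), 0.0)
    new.tn -= draw * w_tn
    new.untested -= draw * (1.0 - w_tn)
    frac = mild_cascade_fractions(p)                  # (SEX, SMOKE, 3)
    new.mild_tp += draw * frac[:, None, :, 0]
    new.mild_fn += draw * frac[:, None, :, 1]
    new.mild_ud += draw * frac[:, None, :, 2]
    return new
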