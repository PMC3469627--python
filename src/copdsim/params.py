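"""Parameter containers for the COPD burden model.

All model inputs live in one :class:`ParamSet`, assembled from the packaged
default parameter file (``data/default_params.yaml``).  Stratification is by
sex (men, women), ten-year age band (40-49, 50-59, 60-69, 70+) and smoking
status (current, previous, never); every stratified quantity is stored as a
numpy array with axes in that order.

The published inputs are kept verbatim; percentage blocks are converted to
fractions at load time and the stage-distribution rows, which are printed
with one-decimal rounding, are renormalized to sum exactly to one.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

SEXES = ("men", "women")
AGE_BANDS = ("40-49", "50-59", "60-69", "70+")
SMOKING = ("current", "previous", "never")
STAGES = ("none", "mild", "moderate", "severe")
COPD_STAGES = ("mild", "moderate", "severe")

N_SEX, N_AGE, N_SMOKE = len(SEXES), len(AGE_BANDS), len(SMOKING)

DAYS_PER_YEAR = 365.25


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants.

    ``errors`` carries every violation found, not just the first.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid parameters:\n  - " + "\n  - ".join(self.errors))


@dataclass
class CalibrationAnchors:
    """Printed anchors the synthetic demography is calibrated against."""

    pop40plus_2011: float = 17.0e6
    pop40plus_2035: float = 24.0e6
    pop70plus_2035: float = 8.0e6
    copd_total_2011: float = 3.45e6

    def validate(self) -> list[str]:
        errs = []
        for name in ("pop40plus_2011", "pop40plus_2035", "pop70plus_2035",
                     "copd_total_2011"):
            if getattr(self, name) <= 0:
                errs.append(f"anchors.{name} must be positive")
        if self.pop70plus_2035 >= self.pop40plus_2035:
            errs.append("anchors.pop70plus_2035 must be below pop40plus_2035")
        return errs


@dataclass
class DemographyParams:
    """Background-population structure and flow rates.

    Entry and net migration stand in for Statistics Canada projections and
    are normally solved by :func:`copdsim.demography.default_demography`.
    """

    age_shares: np.ndarray          # (AGE,) initial band shares of the 40+ total
    men_share: np.ndarray           # (AGE,) male fraction per band
    smoking_mix: np.ndarray         # (SEX, AGE, SMOKE) simplex over smoking status
    aging_rates: np.ndarray         # (AGE,) 1/years transfer to the next band
    background_mortality: np.ndarray  # (SEX, AGE, SMOKE) deaths per person-year
    smoking_cessation_rate: float   # current -> previous, 1/yr
    smoking_initiation_rate: float  # never -> current in 40-49, 1/yr
    entry_rate_per_sex: np.ndarray  # (SEX,) persons/yr entering the 40-49 band
    net_migration_rate: float       # per-capita 1/yr, applied uniformly
    total_pop_2011: float           # initial 40+ population
    initiation_multiplier: float = 1.0

    def initial_population(self) -> np.ndarray:
        """Initial person counts per (sex, age, smoking) subgroup."""
        band = self.age_shares * self.total_pop_2011              # (AGE,)
        sex = np.stack([self.men_share, 1.0 - self.men_share])     # (SEX, AGE)
        return (sex * band)[:, :, None] * self.smoking_mix

    def entry_mix(self) -> np.ndarray:
        """Smoking mix (SEX, SMOKE) of the cohort entering the 40-49 band.

        The current-smoker share is treated as initiation-attributable, so
        the intervention lever ``initiation_multiplier`` scales it, with the
        displaced mass entering as never smokers.
        """
        mix = self.smoking_mix[:, 0, :].copy()
        scaled_current = mix[:, 0] * self.initiation_multiplier
        mix[:, 2] += mix[:, 0] - scaled_current
        mix[:, 0] = scaled_current
        return mix

    def validate(self) -> list[str]:
        errs = []
        if not np.isclose(self.age_shares.sum(), 1.0, atol=1e-9):
            errs.append("demography.age_shares must sum to 1")
        if np.any(self.smoking_mix < 0) or not np.allclose(
                self.smoking_mix.sum(axis=-1), 1.0, atol=1e-9):
            errs.append("demography.smoking_mix must be a simplex per (sex, age)")
        for name in ("aging_rates", "background_mortality", "entry_rate_per_sex"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                errs.append(f"demography.{name} must be non-negative")
        for name in ("smoking_cessation_rate", "smoking_initiation_rate"):
            if getattr(self, name) < 0:
                errs.append(f"demography.{name} must be non-negative")
        if not 0.0 <= self.initiation_multiplier <= 1.0:
            errs.append("demography.initiation_multiplier must be in [0, 1]")
        if self.total_pop_2011 <= 0:
            errs.append("demography.total_pop_2011 must be positive")
        return errs


@dataclass
class DiseaseParams:
    """Stage distributions, symptoms and the spirometry diagnosis cascade."""

    stage_distribution: np.ndarray     # (SEX, AGE, SMOKE, 4) over STAGES
    stage_distribution_printed: np.ndarray  # as published, before renormalization
    symptom_prevalence: np.ndarray     # (SEX, SMOKE, 2): [no_copd, copd]
    spirometry_uptake: float
    spirometry_sensitivity: float
    spirometry_specificity: float
    progression_times: np.ndarray      # (SEX, SMOKE, 2): [mild->mod, mod->sev] years

    def mild_prevalence(self) -> np.ndarray:
        """(SEX, AGE, SMOKE) target mild prevalence, constant over time."""
        return self.stage_distribution[..., 1]

    def progression_hazards(self) -> np.ndarray:
        """(SEX, SMOKE, 2) hazards, reciprocals of the mean progression times."""
        return 1.0 / self.progression_times

    def validate(self) -> list[str]:
        errs = []
        if not np.allclose(self.stage_distribution.sum(axis=-1), 1.0, atol=1e-9):
            errs.append("disease.stage_distribution rows must sum to 1")
        if np.any(self.stage_distribution < 0):
            errs.append("disease.stage_distribution must be non-negative")
        if np.any(self.symptom_prevalence < 0) or np.any(self.symptom_prevalence > 1):
            errs.append("disease.symptom_prevalence must lie in [0, 1]")
        for name in ("spirometry_uptake", "spirometry_sensitivity",
                     "spirometry_specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errs.append(f"disease.{name} must lie in [0, 1], got {v}")
        if np.any(self.progression_times <= 0):
            errs.append("disease.progression_times must be positive")
        return errs


@dataclass
class EventParams:
    """Exacerbation frequencies and the exacerbation-death link."""

    exacerbation_rate: np.ndarray   # (3,) episodes per patient-year by stage
    minor_fraction: np.ndarray      # (3,)
    major_fraction: np.ndarray      # (3,)
    death_prob_per_major: float

    def validate(self) -> list[str]:
        errs = []
        if np.any(self.exacerbation_rate < 0):
            errs.append("events.exacerbation_rate must be non-negative")
        for name in ("minor_fraction", "major_fraction"):
            v = getattr(self, name)
            if np.any(v < 0) or np.any(v > 1):
                errs.append(f"events.{name} must lie in [0, 1]")
        if not np.allclose(self.minor_fraction + self.major_fraction, 1.0,
                           atol=1e-9):
            errs.append("events.minor_fraction + major_fraction must equal 1 "
                        "for every stage")
        if not 0.0 <= self.death_prob_per_major <= 1.0:
            errs.append("events.death_prob_per_major must lie in [0, 1]")
        return errs


@dataclass
class UtilityParams:
    """EQ-5D utility weights and exacerbation episode durations."""

    reference_by_age: np.ndarray    # (AGE,)
    chronic_by_stage: np.ndarray    # (3,)
    minor_exac_by_stage: np.ndarray  # (3,)
    major_exac_by_stage: np.ndarray  # (3,)
    minor_episode_duration: float   # years
    major_episode_duration: float   # years

    def validate(self) -> list[str]:
        errs = []
        for name in ("reference_by_age", "chronic_by_stage",
                     "minor_exac_by_stage", "major_exac_by_stage"):
            v = getattr(self, name)
            if np.any(v < 0) or np.any(v > 1):
                errs.append(f"utilities.{name} must lie in [0, 1]")
        if np.any(self.minor_exac_by_stage > self.chronic_by_stage):
            errs.append("utilities.minor_exac_by_stage must not exceed the "
                        "chronic utility of the same stage")
        if np.any(self.major_exac_by_stage > self.chronic_by_stage):
            errs.append("utilities.major_exac_by_stage must not exceed the "
                        "chronic utility of the same stage")
        for name in ("minor_episode_duration", "major_episode_duration"):
            if getattr(self, name) < 0:
                errs.append(f"utilities.{name} must be non-negative")
        return errs


@dataclass
class EconParams:
    """Unit costs (2011 CAD), discounting and the decision threshold."""

    direct_maintenance: np.ndarray      # (3,) per patient-year by stage
    direct_minor_episode: float
    direct_major_episode: float
    indirect_maintenance: np.ndarray    # (3,)
    indirect_minor_episode: np.ndarray  # (3,)
    indirect_major_episode: np.ndarray  # (3,)
    discount_rate: float = 0.03
    base_year: int = 2011
    wtp_per_qaly: float = 50000.0

    def validate(self) -> list[str]:
        errs = []
        for name in ("direct_maintenance", "direct_minor_episode",
                     "direct_major_episode", "indirect_maintenance",
                     "indirect_minor_episode", "indirect_major_episode"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                errs.append(f"costs.{name} must be non-negative")
        if not 0.0 <= self.discount_rate < 1.0:
            errs.append("economics.discount_rate must lie in [0, 1)")
        if self.wtp_per_qaly < 0:
            errs.append("economics.wtp_per_qaly must be non-negative")
        return errs


@dataclass
class ParamSet:
    """The complete input bundle for one projection run."""

    demography: DemographyParams
    disease: DiseaseParams
    events: EventParams
    utilities: UtilityParams
    economics: EconParams
    anchors: CalibrationAnchors
    year_start: int = 2011
    year_end: int = 2035
    dt: float = 0.25

    def copy(self) -> "ParamSet":
        return copy.deepcopy(self)

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1

    def validate(self) -> list[str]:
        errs = []
        errs += self.anchors.validate()
        errs += self.demography.validate()
        errs += self.disease.validate()
        errs += self.events.validate()
        errs += self.utilities.validate()
        errs += self.economics.validate()
        if self.year_start >= self.year_end:
            errs.append("horizon start must precede end")
        if self.dt <= 0 or abs(round(1.0 / self.dt) * self.dt - 1.0) > 1e-9:
            errs.append("dt must be positive and divide one year exactly")
        return errs

    def require_valid(self) -> "ParamSet":
        errs = self.validate()
        if errs:
            raise ParameterError(errs)
        return self


def _sex_smoke_age(block: dict, scale: float = 1.0) -> np.ndarray:
    """YAML {sex: {smoking: [per-band]}} -> (SEX, AGE, SMOKE) array."""
    out = np.zeros((N_SEX, N_AGE, N_SMOKE))
    for i, sex in enumerate(SEXES):
        for k, smoke in enumerate(SMOKING):
            out[i, :, k] = np.asarray(block[sex][smoke], dtype=float)
    return out * scale


def load_raw_defaults() -> dict:
    """The packaged default parameter file as a plain dict."""
    text = resources.files("copdsim.data").joinpath(
        "default_params.yaml").read_text()
    return yaml.safe_load(text)


def build_paramset(raw: dict | None = None) -> ParamSet:
    """Materialize a :class:`ParamSet` from a raw parameter dict.

    ``raw`` defaults to the packaged parameter file; callers that override
    values should deep-copy :func:`load_raw_defaults`, edit, and pass the
    result here.  Invariants are checked and all violations reported.
    """
    raw = raw if raw is not None else load_raw_defaults()

    anchors = CalibrationAnchors(**{k: float(v)
                                    for k, v in raw["anchors"].items()})

    d = raw["demography"]
    smoking_mix = np.stack([np.asarray(d["smoking_mix"][s], dtype=float)
                            for s in SEXES])
    demography = DemographyParams(
        age_shares=np.asarray(d["age_shares"], dtype=float),
        men_share=np.asarray(d["men_share"], dtype=float),
        smoking_mix=smoking_mix,
        aging_rates=np.asarray(d["aging_rates"], dtype=float),
        background_mortality=_sex_smoke_age(
            raw["background_mortality_per_10k"], scale=1e-4),
        smoking_cessation_rate=float(d["smoking_cessation_rate"]),
        smoking_initiation_rate=float(d["smoking_initiation_rate"]),
        entry_rate_per_sex=np.asarray(d["entry_rate_per_sex"], dtype=float),
        net_migration_rate=float(d["net_migration_rate"]),
        total_pop_2011=anchors.pop40plus_2011,
        initiation_multiplier=float(d.get("initiation_multiplier", 1.0)),
    )

    printed = np.zeros((N_SEX, N_AGE, N_SMOKE, len(STAGES)))
    for i, sex in enumerate(SEXES):
        for k, smoke in enumerate(SMOKING):
            printed[i, :, k, :] = np.asarray(
                raw["stage_distribution_pct"][sex][smoke], dtype=float)
    printed /= 100.0
    stage_distribution = printed / printed.sum(axis=-1, keepdims=True)

    symptom = np.zeros((N_SEX, N_SMOKE, 2))
    for i, sex in enumerate(SEXES):
        for k, smoke in enumerate(SMOKING):
            cell = raw["symptom_prevalence_pct"][sex][smoke]
            symptom[i, k] = [cell["no_copd"] / 100.0, cell["copd"] / 100.0]

    prog = np.zeros((N_SEX, N_SMOKE, 2))
    for i, sex in enumerate(SEXES):
        for k, smoke in enumerate(SMOKING):
            prog[i, k] = np.asarray(
                raw["progression_times_years"][sex][smoke], dtype=float)

    spiro = raw["spirometry"]
    disease = DiseaseParams(
        stage_distribution=stage_distribution,
        stage_distribution_printed=printed,
        symptom_prevalence=symptom,
        spirometry_uptake=float(spiro["uptake"]),
        spirometry_sensitivity=float(spiro["sensitivity"]),
        spirometry_specificity=float(spiro["specificity"]),
        progression_times=prog,
    )

    ex = raw["exacerbations"]
    events = EventParams(
        exacerbation_rate=np.asarray(ex["rate_per_patient_year"], dtype=float),
        minor_fraction=np.asarray(ex["minor_fraction"], dtype=float),
        major_fraction=np.asarray(ex["major_fraction"], dtype=float),
        death_prob_per_major=float(ex["death_prob_per_major"]),
    )

    u = raw["utilities"]
    utilities = UtilityParams(
        reference_by_age=np.asarray(u["reference_by_age"], dtype=float),
        chronic_by_stage=np.asarray(u["chronic_by_stage"], dtype=float),
        minor_exac_by_stage=np.asarray(u["minor_exac_by_stage"], dtype=float),
        major_exac_by_stage=np.asarray(u["major_exac_by_stage"], dtype=float),
        minor_episode_duration=float(u["minor_episode_duration_days"])
        / DAYS_PER_YEAR,
        major_episode_duration=float(u["major_episode_duration_days"])
        / DAYS_PER_YEAR,
    )

    c = raw["costs_cad_2011"]
    econ_block = raw["economics"]
    economics = EconParams(
        direct_maintenance=np.asarray(c["direct_maintenance"], dtype=float),
        direct_minor_episode=float(c["direct_minor_episode"]),
        direct_major_episode=float(c["direct_major_episode"]),
        indirect_maintenance=np.asarray(c["indirect_maintenance"], dtype=float),
        indirect_minor_episode=np.asarray(c["indirect_minor_episode"],
                                          dtype=float),
        indirect_major_episode=np.asarray(c["indirect_major_episode"],
                                          dtype=float),
        discount_rate=float(econ_block["discount_rate"]),
        base_year=int(econ_block["base_year"]),
        wtp_per_qaly=float(econ_block["wtp_per_qaly"]),
    )

    ps = ParamSet(
        demography=demography,
        disease=disease,
        events=events,
        utilities=utilities,
        economics=economics,
        anchors=anchors,
        year_start=int(raw["horizon"]["start"]),
        year_end=int(raw["horizon"]["end"]),
        dt=float(raw["dt"]),
    )
    return ps.require_valid()


def default_paramset() -> ParamSet:
    """The packaged default parameter set (uncalibrated demography)."""
    return build_paramset()
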