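"""Synthetic demographic projection for Canadian adults 40+.

The model needs the 2011-2035 background population by sex, ten-year age
band and smoking status.  The official projections behind the original
analysis are not reproduced here; instead a stock-and-flow population with
entry into the 40-49 band, band-to-band aging, uniform per-capita net
migration, subgroup background mortality and smoking initiation/cessation
is calibrated so that its trajectory matches the printed anchors: a 40+
population growing from about 17 to about 24 million over 2011-2035 with
the 70+ group doubling to about 8 million, and 3.45 million prevalent COPD
cases at baseline.

Calibration solves two scalars -- the entry rate into the 40-49 band and
the net migration rate -- against the two 2035 population anchors, and one
smoking-mix shift (current vs. never) against the baseline COPD count.
Everything is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
from scipy import optimize

from .params import (CalibrationAnchors, DemographyParams, ParamSet,
                     default_paramset)

logger = logging.getLogger(__name__)


class CalibrationError(RuntimeError):
    """Raised when the anchors cannot be met within tolerance."""


@dataclass
class DemographicFlows:
    """Per-step person flows, for conservation accounting."""

    entries: float
    migration: float
    deaths: float


def step_compartments(arrays: dict[str, np.ndarray], dp: DemographyParams,
                      dt: float, entry_split: dict[str, np.ndarray] | None = None,
                      ) -> tuple[dict[str, np.ndarray], DemographicFlows]:
    """Advance every compartment array through one demographic Euler step.

    Applies, in order: background mortality, aging transfers, smoking
    cessation (current to previous) and initiation (never to current, 40-49
    band only), net migration, and entry of new 40-year-olds.  All flows act
    proportionally on each compartment, so people carry their disease and
    diagnosis state across subgroup moves.  ``entry_split`` maps compartment
    names to (SEX, SMOKE) fractions of the entering cohort (default: all
    entrants into the first compartment listed).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    mu = dp.background_mortality * dt
    ces = dp.smoking_cessation_rate * dt
    ini = dp.smoking_initiation_rate * dp.initiation_multiplier * dt
    age = dp.aging_rates * dt
    outflow_cap = mu + ces + age[None, :, None]
    if np.any(outflow_cap > 1.0) or ini > 1.0:
        raise ValueError("dt too large: combined outflows exceed a stock; "
                         "use a smaller dt")

    new: dict[str, np.ndarray] = {}
    deaths = 0.0
    migration = 0.0
    for name, x in arrays.items():
        d = x * mu
        deaths += float(d.sum())
        y = x - d
        # aging: band b loses y*age[b] to band b+1 (70+ absorbs)
        moved = y * age[None, :, None]
        y = y - moved
        y[:, 1:, :] += moved[:, :-1, :]
        # smoking transitions
        quit_ = y[:, :, 0] * ces
        y[:, :, 0] -= quit_
        y[:, :, 1] += quit_
        start = y[:, 0, 2] * ini
        y[:, 0, 2] -= start
        y[:, 0, 0] += start
        # net migration, proportional to stock (keeps composition)
        mig = y * dp.net_migration_rate * dt
        migration += float(mig.sum())
        y = y + mig
        new[name] = y

    entries = float(dp.entry_rate_per_sex.sum() * dt)
    entry_mix = dp.entry_mix()                            # (SEX, SMOKE)
    entrant = dp.entry_rate_per_sex[:, None] * entry_mix * dt
    if entry_split is None:
        first = next(iter(new))
        new[first][:, 0, :] += entrant
    else:
        for name, frac in entry_split.items():
            new[name][:, 0, :] += entrant * frac
    return new, DemographicFlows(entries=entries, migration=migration,
                                 deaths=deaths)


def step_population(pop: np.ndarray, dp: DemographyParams, dt: float
                    ) -> tuple[np.ndarray, DemographicFlows]:
    """One demographic step on a bare (SEX, AGE, SMOKE) population array."""
    out, flows = step_compartments({"pop": pop}, dp, dt)
    return out["pop"], flows


def project_population(dp: DemographyParams, years: int, dt: float
                       ) -> np.ndarray:
    """Population trajectory; shape (years+1, SEX, AGE, SMOKE)."""
    steps = round(1.0 / dt)
    pop = dp.initial_population()
    out = [pop]
    for _ in range(years):
        for _ in range(steps):
            pop, _ = step_population(pop, dp, dt)
        out.append(pop)
    return np.stack(out)


def _with_rates(dp: DemographyParams, entry: float, mig: float
                ) -> DemographyParams:
    new = DemographyParams(**{f.name: getattr(dp, f.name) for f in fields(dp)})
    sex_split = dp.entry_rate_per_sex / dp.entry_rate_per_sex.sum()
    new.entry_rate_per_sex = entry * sex_split
    new.net_migration_rate = mig
    return new


def shift_smoking_mix(mix: np.ndarray, lam: float) -> np.ndarray:
    """Scale the current-smoker share by ``lam``, balancing with never."""
    out = mix.copy()
    out[..., 2] += out[..., 0] * (1.0 - lam)
    out[..., 0] *= lam
    if np.any(out < 0):
        raise ValueError("smoking-mix shift leaves a negative share")
    return out


def baseline_copd_total(ps: ParamSet) -> float:
    """Prevalent COPD cases implied by the 2011 population and stage mix."""
    pop = ps.demography.initial_population()
    return float((pop * (1.0 - ps.disease.stage_distribution[..., 0])).sum())


def default_demography(anchors: CalibrationAnchors | None = None,
                       ps: ParamSet | None = None,
                       tol: float = 0.02) -> ParamSet:
    """Calibrate the demography of ``ps`` (default parameter set) to the anchors.

    Returns a new :class:`ParamSet` whose projection reproduces all four
    anchors within ``tol`` relative error; raises :class:`CalibrationError`
    naming the violated anchor otherwise.  Deterministic given the anchors.
    """
    ps = (ps or default_paramset()).copy()
    if anchors is not None:
        ps.anchors = anchors
        ps.demography.total_pop_2011 = anchors.pop40plus_2011
    anchors = ps.anchors
    errs = anchors.validate()
    if errs:
        raise CalibrationError("invalid anchors: " + "; ".join(errs))
    years = ps.year_end - ps.year_start

    # 1) smoking mix shift against the baseline COPD count (independent of
    # the flow rates -- it only involves the 2011 stocks).
    def copd_resid(lam: float) -> float:
        trial = ps.copy()
        trial.demography.smoking_mix = shift_smoking_mix(
            ps.demography.smoking_mix, lam)
        return baseline_copd_total(trial) - anchors.copd_total_2011

    lo, hi = 0.05, 2.0
    hi = min(hi, float(1.0 / ps.demography.smoking_mix[..., 0].max()) - 1e-9)
    try:
        lam = optimize.brentq(copd_resid, lo, hi, xtol=1e-10)
    except ValueError as exc:
        raise CalibrationError(
            "anchor copd_total_2011 unreachable by shifting the smoking mix "
            f"within [{lo}, {hi:.2f}]") from exc
    ps.demography.smoking_mix = shift_smoking_mix(ps.demography.smoking_mix,
                                                  lam)

    # 2) entry + migration against the 2035 population anchors.
    def resid(x: np.ndarray) -> np.ndarray:
        dp = _with_rates(ps.demography, float(x[0]), float(x[1]))
        traj = project_population(dp, years, ps.dt)
        final = traj[-1]
        return np.array([
            final.sum() / anchors.pop40plus_2035 - 1.0,
            final[:, 3, :].sum() / anchors.pop70plus_2035 - 1.0,
        ])

    x0 = np.array([float(ps.demography.entry_rate_per_sex.sum()),
                   ps.demography.net_migration_rate])
    sol = optimize.least_squares(resid, x0, bounds=([0.0, -0.05], [5e6, 0.05]),
                                 xtol=1e-12, ftol=1e-12)
    entry, mig = float(sol.x[0]), float(sol.x[1])
    ps.demography = _with_rates(ps.demography, entry, mig)

    traj = project_population(ps.demography, years, ps.dt)
    checks = {
        "pop40plus_2011": (float(traj[0].sum()), anchors.pop40plus_2011),
        "pop40plus_2035": (float(traj[-1].sum()), anchors.pop40plus_2035),
        "pop70plus_2035": (float(traj[-1][:, 3, :].sum()),
                           anchors.pop70plus_2035),
        "copd_total_2011": (baseline_copd_total(ps), anchors.copd_total_2011),
    }
    bad = {k: v for k, (v, target) in checks.items()
           if abs(v / target - 1.0) > tol}
    if bad:
        raise CalibrationError(
            "anchors violated after calibration: "
            + "; ".join(f"{k}: got {v:.4g}, wanted {checks[k][1]:.4g}"
                        for k, v in bad.items()))
    for k, (v, target) in checks.items():
        logger.info("calibration %s: %.4g (target %.4g, residual %+.2f%%)",
                    k, v, target, 100.0 * (v / target - 1.0))
    return ps
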