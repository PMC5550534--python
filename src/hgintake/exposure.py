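"""Per-subject mercury intake arithmetic and risk characterization.

Intake flows from a meal schedule (which species, which state, what portion
mass, which day) and per-species tissue concentrations:

    meal intake [μg]   = conc [mg/kg] x portion mass [kg] x 1000
    daily intake       = total / number of fish-consumption days
    weekly intake      = total / number of schedule weeks
    EDI [μg/kg bw/day] = daily / body weight
    EWI [μg/kg bw/wk]  = weekly / body weight
    hazard index       = EWI / PTWI;  risk index [%] = 100 x HI

Total mercury is converted to methylmercury by a fixed fraction (default
1.0, i.e. the conservative assumption that all fish-tissue Hg is MeHg)
before comparison with MeHg-based limits.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, replace

from ._stats import describe
from .constants import (MPC_MG_PER_KG, NRC_LIMIT, PTWI_JAPAN, PTWI_MEHG,
                        PTWI_THG, STATES)

# --- Domain types ----------------------------------------------------------


@dataclass(frozen=True)
class MealEvent:
    """One fish meal: 1-based study day, species/state, edible mass in kg."""

    day: int
    species_id: str
    state: str
    mass: float

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValueError(f"day must be >= 1, got {self.day}")
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        if self.mass < 0:
            raise ValueError(f"negative meal mass {self.mass}")


@dataclass(frozen=True)
class MealSchedule:
    """An ordered multi-week meal plan.

    ``consumption_days`` counts distinct days with at least one meal; it can
    never exceed 7 days per week of schedule.
    """

    events: tuple[MealEvent, ...]
    n_weeks: int

    def __init__(self, events: Sequence[MealEvent], n_weeks: int) -> None:
        object.__setattr__(self, "events",
                           tuple(sorted(events, key=lambda e: e.day)))
        object.__setattr__(self, "n_weeks", int(n_weeks))
        if self.n_weeks < 1:
            raise ValueError(f"n_weeks must be >= 1, got {n_weeks}")
        if self.consumption_days > 7 * self.n_weeks:
            raise ValueError("more consumption days than days in the schedule")

    @property
    def consumption_days(self) -> int:
        return len({e.day for e in self.events})

    @property
    def total_mass(self) -> float:
        return sum(e.mass for e in self.events)


@dataclass(frozen=True)
class Subject:
    """A study participant.

    Body weight is taken as given when present, otherwise derived as
    BMI x height². When both routes are available they must agree to
    within 0.5 kg.
    """

    subject_id: str
    body_weight: float | None = None
    bmi: float | None = None
    height: float | None = None
    smoker: bool = False
    amalgam_fillings: int = 0

    def __post_init__(self) -> None:
        if self.amalgam_fillings < 0:
            raise ValueError("amalgam_fillings must be >= 0")
        if self.body_weight is None:
            if self.bmi is None or self.height is None:
                raise ValueError(
                    f"subject {self.subject_id!r}: need body_weight or bmi+height")
            object.__setattr__(self, "body_weight", self.bmi * self.height ** 2)
        elif self.bmi is not None and self.height is not None:
            derived = self.bmi * self.height ** 2
            if abs(self.body_weight - derived) > 0.5:
                raise ValueError(
                    f"subject {self.subject_id!r}: body weight {self.body_weight:.1f} kg "
                    f"inconsistent with BMI x height² = {derived:.1f} kg")
        if self.body_weight is None or self.body_weight <= 0:
            raise ValueError(
                f"subject {self.subject_id!r}: non-positive body weight")


@dataclass(frozen=True)
class ThresholdSet:
    """Regulatory limits and the THg->MeHg fraction assumption.

    All intake limits in μg/kg bw/week; ``mpc`` in mg/kg wet weight.
    ``mehg_fraction`` scales total-Hg intake to MeHg before limit
    comparison; 1.0 treats all tissue Hg as MeHg (the conservative default),
    0.9 is the commonly stated alternative.
    """

    ptwi_mehg: float = PTWI_MEHG
    ptwi_thg: float = PTWI_THG
    nrc_limit: float = NRC_LIMIT
    mpc: float = MPC_MG_PER_KG
    ptwi_japan: float = PTWI_JAPAN
    mehg_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ptwi_mehg", "ptwi_thg", "nrc_limit", "mpc", "ptwi_japan"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.mehg_fraction <= 1:
            raise ValueError("mehg_fraction must be in (0, 1]")

    def with_fraction(self, fraction: float) -> "ThresholdSet":
        return replace(self, mehg_fraction=fraction)


@dataclass(frozen=True)
class ExposureResult:
    """Per-subject intake totals and risk metrics over one schedule."""

    subject_id: str
    total_intake: float    # μg over the whole schedule (THg)
    daily_intake: float    # μg per consumption day
    weekly_intake: float   # μg/week
    edi: float             # μg MeHg/kg bw/day
    ewi: float             # μg MeHg/kg bw/week
    pct_ptwi: float        # % of PTWI (= 100 x hazard_index)
    hazard_index: float    # EWI / PTWI
    exceeds_ptwi: bool
    exceeds_nrc: bool


# --- Intake arithmetic -----------------------------------------------------


def meal_intake(conc: float, mass: float) -> float:
    """Hg mass ingested in one meal, μg: conc (mg/kg) x mass (kg) x 1000."""
    if conc < 0:
        raise ValueError(f"negative concentration {conc}")
    if mass < 0:
        raise ValueError(f"negative mass {mass}")
    return conc * mass * 1000.0


def schedule_total_intake(schedule: MealSchedule,
                          conc_lookup: Mapping[tuple[str, str], float]) -> float:
    """Total Hg intake over the schedule, μg (sum of per-meal intakes)."""
    total = 0.0
    for event in schedule.events:
        key = (event.species_id, event.state)
        if key not in conc_lookup:
            raise KeyError(
                f"no concentration for species {event.species_id!r} "
                f"state {event.state!r}")
        total += meal_intake(conc_lookup[key], event.mass)
    return total


def daily_intake(total: float, schedule: MealSchedule, *,
                 calendar_days: bool = False) -> float:
    """Mean daily intake, μg/day.

    Divides by fish-consumption days by default; ``calendar_days=True``
    divides by 7 x n_weeks instead.
    """
    days = 7 * schedule.n_weeks if calendar_days else schedule.consumption_days
    if days < 1:
        raise ValueError("schedule has no consumption days")
    return total / days


def weekly_intake(total: float, schedule: MealSchedule) -> float:
    """Mean weekly intake, μg/week: total over the schedule / number of weeks."""
    return total / schedule.n_weeks


def edi(daily: float, body_weight: float) -> float:
    """Estimated daily intake per kg body weight, μg/kg bw/day."""
    if body_weight <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight}")
    return daily / body_weight


def ewi(weekly: float, body_weight: float) -> float:
    """Estimated weekly intake per kg body weight, μg/kg bw/week."""
    if body_weight <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight}")
    return weekly / body_weight


def hazard_index(ewi_value: float, ptwi: float) -> float:
    """EWI / PTWI; values >= 1 mean the guideline is met or exceeded."""
    if ptwi <= 0:
        raise ValueError(f"ptwi must be positive, got {ptwi}")
    return ewi_value / ptwi


def percent_ptwi(ewi_value: float, ptwi: float) -> float:
    """Risk index: EWI as a percentage of the PTWI."""
    return 100.0 * hazard_index(ewi_value, ptwi)


def weekly_mass_equivalent(rate: float, body_weight: float) -> float:
    """Convert a weekly per-kg rate (μg/kg bw/week) to mg Hg/week for one person."""
    if body_weight <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight}")
    return rate * body_weight / 1000.0


def mehg_from_thg(thg: float, fraction: float) -> float:
    """MeHg amount from a total-Hg amount via the assumed MeHg fraction."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return thg * fraction


# --- Cohort-level exposure -------------------------------------------------


def subject_exposure(subject: Subject, schedule: MealSchedule,
                     conc_lookup: Mapping[tuple[str, str], float],
                     thresholds: ThresholdSet | None = None) -> ExposureResult:
    """Full intake and risk characterization for one subject."""
    thresholds = thresholds or ThresholdSet()
    total = schedule_total_intake(schedule, conc_lookup)
    daily = daily_intake(total, schedule)
    weekly = weekly_intake(total, schedule)
    bw = subject.body_weight
    assert bw is not None
    mehg_daily = mehg_from_thg(daily, thresholds.mehg_fraction)
    mehg_weekly = mehg_from_thg(weekly, thresholds.mehg_fraction)
    ewi_val = ewi(mehg_weekly, bw)
    hi = hazard_index(ewi_val, thresholds.ptwi_mehg)
    return ExposureResult(
        subject_id=subject.subject_id,
        total_intake=total,
        daily_intake=daily,
        weekly_intake=weekly,
        edi=edi(mehg_daily, bw),
        ewi=ewi_val,
        pct_ptwi=100.0 * hi,
        hazard_index=hi,
        exceeds_ptwi=ewi_val > thresholds.ptwi_mehg,
        exceeds_nrc=ewi_val > thresholds.nrc_limit,
    )


def cohort_exposure(cohort: Sequence[Subject], schedule: MealSchedule,
                    conc_lookup: Mapping[tuple[str, str], float],
                    thresholds: ThresholdSet | None = None,
                    ) -> tuple[list[ExposureResult], dict[str, dict[str, float]]]:
    """Exposure for every subject plus a cohort distribution summary.

    Returns ``(results, summary)`` where ``summary`` holds mean/median/
    p95/min/max of EWI and of %PTWI under the package percentile convention.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    results = [subject_exposure(s, schedule, conc_lookup, thresholds)
               for s in cohort]
    summary = {
        "ewi": describe([r.ewi for r in results]),
        "pct_ptwi": describe([r.pct_ptwi for r in results]),
    }
    return results, summary


def exceedance_fraction(results: Sequence[ExposureResult], limit: float, *,
                        inclusive: bool = False) -> float:
    """Fraction of subjects whose EWI exceeds ``limit`` (strict by default).

    With the default strict comparison a subject sitting exactly at the
    limit counts as compliant; ``inclusive=True`` flips that convention.
    """
    if not results:
        raise ValueError("no exposure results")
    if inclusive:
        count = sum(1 for r in results if r.ewi >= limit)
    else:
        count = sum(1 for r in results if r.ewi > limit)
    return count / len(results)
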