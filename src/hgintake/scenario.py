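"""Hypothetical consumption-pattern projections.

Answers "what if" questions around the intervention: weekly per-kg intake
for a reference person eating a given species a fixed number of times per
week, the EWI of an all-one-species week, and the inverse problem — how
much fish of a given contamination a person can eat weekly without
exceeding an intake limit.

Scenarios default to fried-state concentrations, matching how the
intervention fish were actually consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exposure import ThresholdSet, meal_intake


@dataclass(frozen=True)
class Scenario:
    """A single-species consumption pattern for one reference person."""

    species_id: str
    portion_mass: float          # kg per meal
    body_weight: float           # kg
    meals_per_week: int = 0
    state: str = "fried"
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)

    def __post_init__(self) -> None:
        if self.portion_mass < 0:
            raise ValueError("portion_mass must be >= 0")
        if self.body_weight <= 0:
            raise ValueError("body_weight must be positive")
        if self.meals_per_week < 0:
            raise ValueError("meals_per_week must be >= 0")

    def weekly_ewi(self, conc: float) -> float:
        return reference_person_weekly(conc, self.portion_mass,
                                       self.meals_per_week, self.body_weight)


def reference_person_weekly(conc: float, portion_mass: float,
                            meals_per_week: int, body_weight: float) -> float:
    """Weekly per-kg Hg intake for a reference person, μg/kg bw/week.

    ``meals_per_week`` portions of ``portion_mass`` kg at tissue
    concentration ``conc`` mg/kg, normalised by body weight.
    """
    if meals_per_week < 0:
        raise ValueError("meals_per_week must be >= 0")
    if body_weight <= 0:
        raise ValueError("body_weight must be positive")
    return meals_per_week * meal_intake(conc, portion_mass) / body_weight


def single_species_week(conc: float, portion_mass: float, days: int,
                        body_weight: float) -> float:
    """EWI for a week of eating only one species, one portion per day.

    ``days`` must lie in [0, 7]: the quantity is per week. Multi-week
    patterns belong in a MealSchedule.
    """
    if not 0 <= days <= 7:
        raise ValueError(f"days must be in [0, 7], got {days}")
    if body_weight <= 0:
        raise ValueError("body_weight must be positive")
    return days * meal_intake(conc, portion_mass) / body_weight


def max_allowable_weekly_mass(conc: float, limit: float,
                              body_weight: float) -> float:
    """Largest weekly fish mass (kg) whose intake exactly meets ``limit``.

    Inverts the EWI arithmetic: mass = limit x body weight / (conc x 1000).
    """
    if conc <= 0:
        raise ValueError("no finite bound: concentration must be positive")
    if body_weight <= 0:
        raise ValueError("body_weight must be positive")
    if limit < 0:
        raise ValueError("limit must be >= 0")
    return limit * body_weight / (conc * 1000.0)
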