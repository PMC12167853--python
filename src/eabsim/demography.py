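"""Tree-population bookkeeping.

Deterministic cohort demography: annual mortality with a ceiling rounding
convention, the post-planting survival schedule, linear DBH growth, and the
calibration helper that recovers the initial median ash DBH from a printed
basal-area figure.

The rounding convention is load-bearing: survivor counts are ``ceil(N * s)``
at every cohort-year transition.  Floor or round-half-even do not reproduce
the reference trajectories this engine is validated against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple, Union

from .errors import ParameterError

__all__ = [
    "PRE_EXISTING",
    "DemographyParams",
    "TreeCohort",
    "apply_annual_mortality",
    "survival_rate",
    "grow_dbh",
    "advance_cohort",
    "calibrate_initial_dbh",
]

#: Sentinel planting year for cohorts that predate the simulation.
PRE_EXISTING = "pre-existing"

# Default post-planting survival schedule: (years since planting, survival).
_DEFAULT_WARRANTY = ((1, 0.915), (2, 0.883), (3, 0.958), (4, 0.939))


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class DemographyParams:
    """All demographic rates and the initial population description.

    Defaults are the reference parameterization: 1,490 pre-existing ash at a
    calibrated median DBH of 27.181 cm, 20%/yr mortality when uninjected,
    2.8%/yr under injection, 0.85%/yr background mortality, and a four-year
    post-planting survival schedule for newly planted non-ash stock.
    """

    natural_mortality: float = 0.0085
    injected_ash_mortality: float = 0.028
    noninjected_ash_mortality: float = 0.20
    ash_growth: float = 0.3
    nonash_growth: float = 0.47
    warranty_survival: Tuple[Tuple[int, float], ...] = _DEFAULT_WARRANTY
    planting_dbh: float = 6.0
    initial_ash_count: int = 1490
    initial_ash_dbh: float = 27.181

    def __post_init__(self) -> None:
        for name in ("natural_mortality", "injected_ash_mortality",
                     "noninjected_ash_mortality"):
            _check_fraction(name, getattr(self, name))
        for name in ("ash_growth", "nonash_growth"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.planting_dbh <= 0 or self.initial_ash_dbh <= 0:
            raise ParameterError("planting_dbh and initial_ash_dbh must be > 0")
        if self.initial_ash_count < 0 or self.initial_ash_count != int(self.initial_ash_count):
            raise ParameterError("initial_ash_count must be a non-negative integer")
        schedule = tuple((int(y), float(s)) for y, s in self.warranty_survival)
        years = [y for y, _ in schedule]
        if years != list(range(1, len(years) + 1)):
            raise ParameterError(
                "warranty_survival must cover consecutive years starting at 1")
        for y, s in schedule:
            _check_fraction(f"warranty_survival[year {y}]", s)
        object.__setattr__(self, "warranty_survival", schedule)

    @property
    def warranty_years(self) -> int:
        return len(self.warranty_survival)


@dataclass(frozen=True)
class TreeCohort:
    """A group of identically parameterized trees.

    ``planting_year`` is an integer simulation year for planted cohorts, or
    :data:`PRE_EXISTING` for the initial population.
    """

    count: int
    dbh: float
    species_class: str = "ash"
    injected: bool = False
    planting_year: Union[int, str] = PRE_EXISTING

    def __post_init__(self) -> None:
        if self.count < 0 or self.count != int(self.count):
            raise ParameterError("cohort count must be a non-negative integer")
        if self.dbh < 0:
            raise ParameterError("cohort dbh must be >= 0")
        if self.species_class not in ("ash", "nonash"):
            raise ParameterError(
                f"species_class must be 'ash' or 'nonash', got {self.species_class!r}")
        if self.species_class == "nonash" and self.injected:
            raise ParameterError("non-ash cohorts cannot be injected")
        if self.planting_year != PRE_EXISTING and not isinstance(self.planting_year, int):
            raise ParameterError(
                "planting_year must be an int or the PRE_EXISTING sentinel")

    @property
    def is_planted(self) -> bool:
        return isinstance(self.planting_year, int)

    def age_at(self, year: int) -> Optional[int]:
        """Years since planting at the end of `year` (planting year = age 1)."""
        if not self.is_planted:
            return None
        return year - self.planting_year + 1


def apply_annual_mortality(count: int, rate: float) -> int:
    """Survivors of one year of mortality at `rate`, ceiling-rounded.

    Returns ``ceil(count * (1 - rate))``.  Identity at rate 0; never
    increases the count.
    """
    if count < 0 or count != int(count):
        raise ParameterError("count must be a non-negative integer")
    _check_fraction("rate", rate)
    return math.ceil(int(count) * (1.0 - rate))


def survival_rate(years_since_planting: int, params: DemographyParams) -> float:
    """Annual survival for a planted tree of the given age.

    Ages within the post-planting schedule use the scheduled survival; older
    trees revert to ``1 - natural_mortality``.
    """
    if years_since_planting < 1:
        raise ParameterError("years_since_planting must be >= 1")
    if years_since_planting <= params.warranty_years:
        return params.warranty_survival[years_since_planting - 1][1]
    return 1.0 - params.natural_mortality


def grow_dbh(dbh: float, growth: float) -> float:
    """One year of linear DBH growth."""
    if dbh < 0 or growth < 0:
        raise ParameterError("dbh and growth must be >= 0")
    return dbh + growth


def _cohort_survival(cohort: TreeCohort, year: int, params: DemographyParams) -> float:
    if cohort.is_planted:
        return survival_rate(cohort.age_at(year), params)
    if cohort.species_class == "ash":
        rate = (params.injected_ash_mortality if cohort.injected
                else params.noninjected_ash_mortality)
        return 1.0 - rate
    return 1.0 - params.natural_mortality


def advance_cohort(
    cohort: TreeCohort,
    year: int,
    params: DemographyParams,
    mortality_override: Optional[float] = None,
) -> TreeCohort:
    """Advance one cohort through one simulated year.

    Applies species/age-appropriate survival with ceiling rounding and one
    increment of DBH growth.  ``mortality_override`` replaces the derived
    mortality rate when given (e.g. to suppress mortality in a year whose
    deaths are subsumed by scheduled removals).
    """
    if year < 1:
        raise ParameterError("year must be >= 1")
    if mortality_override is not None:
        _check_fraction("mortality_override", mortality_override)
        survival = 1.0 - mortality_override
    else:
        survival = _cohort_survival(cohort, year, params)
    growth = params.ash_growth if cohort.species_class == "ash" else params.nonash_growth
    return replace(
        cohort,
        count=math.ceil(cohort.count * survival),
        dbh=grow_dbh(cohort.dbh, growth),
    )


def calibrate_initial_dbh(
    year1_basal_printed: float, year1_count: int, growth: float
) -> float:
    """Invert the printed-basal formula to recover the initial median DBH.

    Solves ``pi * ((d0 + growth) / 2)**2 * year1_count / 1000 ==
    year1_basal_printed`` for ``d0``.  Used once to fix the package default
    ``initial_ash_dbh``; exposed so the constant can be re-derived.
    """
    if year1_basal_printed <= 0 or year1_count <= 0 or growth < 0:
        raise ParameterError("basal and count must be > 0, growth >= 0")
    per_tree_area = year1_basal_printed * 1000.0 / year1_count  # cm^2
    return 2.0 * math.sqrt(per_tree_area / math.pi) - growth
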