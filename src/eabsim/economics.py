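"""Monetary computation: event costs, warranty logic, trunk-formula appraisal,
inflation and discounting.

Conventions (see README for rationale):

* Stumping has no separate price schedule and is folded into the removal
  bracket cost.
* Pruning bills a quarter of every living cohort each year; injection bills
  half of the injected ash population each year.  Cycle fractions are kept
  as exact (unrounded) tree counts.
* Present value compounds inflation then discounting: factor
  ``((1 + inflation) / (1 + discount)) ** t`` with ``t`` counted from Year 0
  and costs booked at end of year (Year 1 gets exponent 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple, Union

from .errors import ConfigError, ParameterError

__all__ = [
    "CostSchedule",
    "RatingSet",
    "EconParams",
    "CostBreakdown",
    "bracket_cost",
    "injection_cost",
    "planting_charge",
    "ctla_value",
    "present_value",
    "discount_factor",
    "annual_cost",
]

NEW_PLANTING = "new"

# (dbh upper bound in cm, cost in $); the final bracket is open-ended.
_DEFAULT_REMOVAL = ((20, 105.0), (40, 305.0), (60, 855.0), (80, 1450.0),
                    (100, 2950.0), (120, 2950.0), (math.inf, 5700.0))
_DEFAULT_PRUNING = ((20, 60.0), (40, 118.0), (60, 268.0), (80, 460.0),
                    (100, 610.0), (120, 710.0), (math.inf, 862.0))

Brackets = Tuple[Tuple[float, float], ...]
CountDbh = Tuple[float, float]


def _normalize_brackets(name: str, brackets) -> Brackets:
    out = tuple((float(u), float(c)) for u, c in brackets)
    if not out:
        raise ConfigError(f"{name}: bracket schedule is empty")
    uppers = [u for u, _ in out]
    if any(b <= a for a, b in zip(uppers, uppers[1:])):
        raise ConfigError(f"{name}: bracket upper bounds must be strictly increasing")
    if any(c < 0 for _, c in out):
        raise ConfigError(f"{name}: bracket costs must be >= 0")
    return out


@dataclass(frozen=True)
class CostSchedule:
    """DBH-bracketed removal/pruning prices plus unit costs."""

    removal_brackets: Brackets = _DEFAULT_REMOVAL
    pruning_brackets: Brackets = _DEFAULT_PRUNING
    injection_per_cm: float = 3.325
    planting_cost: float = 849.91
    new_tree_unit_cost: float = 4.50  # $/cm^2 of trunk area

    def __post_init__(self) -> None:
        object.__setattr__(self, "removal_brackets",
                           _normalize_brackets("removal_brackets", self.removal_brackets))
        object.__setattr__(self, "pruning_brackets",
                           _normalize_brackets("pruning_brackets", self.pruning_brackets))
        for name in ("injection_per_cm", "planting_cost", "new_tree_unit_cost"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass(frozen=True)
class RatingSet:
    """Condition / functional-limitation / external-limitation ratings."""

    condition: float
    functional: float
    external: float

    def __post_init__(self) -> None:
        for name in ("condition", "functional", "external"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"rating {name} must be in [0, 1], got {v!r}")

    @property
    def product(self) -> float:
        return self.condition * self.functional * self.external


@dataclass(frozen=True)
class EconParams:
    inflation: float = 0.02
    discount: float = 0.0283
    ash_ratings: RatingSet = field(
        default_factory=lambda: RatingSet(0.50, 0.75, 0.10))
    nonash_ratings: RatingSet = field(
        default_factory=lambda: RatingSet(0.75, 0.75, 0.90))
    cost_schedule: CostSchedule = field(default_factory=CostSchedule)

    def __post_init__(self) -> None:
        if self.inflation < 0 or self.discount < 0:
            raise ParameterError("inflation and discount must be >= 0")

    def ratings_for(self, species_class: str) -> RatingSet:
        return self.ash_ratings if species_class == "ash" else self.nonash_ratings


def bracket_cost(dbh: float, brackets: Brackets) -> float:
    """Price of the first bracket whose upper bound is >= dbh.

    Upper bounds are inclusive (a 20 cm tree falls in a 0-20 bracket); DBH
    beyond the last finite bound falls in the final, open-ended bracket.
    """
    if dbh < 0:
        raise ParameterError("dbh must be >= 0")
    if not brackets:
        raise ConfigError("empty bracket schedule")
    for upper, cost in brackets:
        if dbh <= upper:
            return cost
    return brackets[-1][1]


def injection_cost(dbh: float, rate: float) -> float:
    """Per-tree injection cost: $/cm times DBH."""
    if dbh < 0:
        raise ParameterError("dbh must be >= 0")
    return rate * dbh


def planting_charge(years_since_planting: Union[int, str], cost: float) -> float:
    """Charge for replacing a dead planted tree, or for a scheduled planting.

    Deaths within the two-year warranty are replaced free of charge; from
    year 3 the full planting cost applies, as it does for every scheduled
    new planting (pass :data:`NEW_PLANTING`).
    """
    if years_since_planting == NEW_PLANTING:
        return cost
    if not isinstance(years_since_planting, int) or years_since_planting < 1:
        raise ParameterError("years_since_planting must be >= 1 or 'new'")
    return 0.0 if years_since_planting <= 2 else cost


def ctla_value(dbh: float, nt: float, ratings: RatingSet) -> float:
    """Trunk-formula appraisal of a single tree.

    ``(dbh / 2)**2 * pi * nt * condition * functional * external`` with
    ``nt`` the replacement cost of new trunk area in $/cm^2.
    """
    if dbh < 0:
        raise ParameterError("dbh must be >= 0")
    return (dbh / 2.0) ** 2 * math.pi * nt * ratings.product


def discount_factor(t: float, econ: EconParams) -> float:
    """Compound inflation-then-discount factor at t years from Year 0."""
    if t < 0:
        raise ParameterError("t must be >= 0")
    return ((1.0 + econ.inflation) / (1.0 + econ.discount)) ** t


def present_value(nominal: float, t: float, econ: EconParams) -> float:
    """Present value of a nominal amount booked t years from Year 0."""
    return nominal * discount_factor(t, econ)


@dataclass(frozen=True)
class CostBreakdown:
    """Nominal cost components for one simulated year plus the PV total."""

    removal: float
    pruning: float
    injection: float
    planting: float
    year: int
    pv_factor: float

    @property
    def total_nominal(self) -> float:
        return self.removal + self.pruning + self.injection + self.planting

    @property
    def total_pv(self) -> float:
        return self.total_nominal * self.pv_factor


def annual_cost(
    removals: Sequence[CountDbh],
    living: Sequence[CountDbh],
    injected: Sequence[CountDbh],
    plantings: int,
    replacement_deaths: int,
    year: int,
    econ: EconParams,
) -> CostBreakdown:
    """Cost of one year's events.

    Parameters are (count, dbh) pairs per cohort: ``removals`` are trees
    removed (and stumped) this year, ``living`` the end-of-year standing
    population (a quarter is pruned), ``injected`` the injected ash (half
    are injected).  ``plantings`` are scheduled new plantings and
    ``replacement_deaths`` post-warranty deaths of planted stock, both
    billed at the full planting cost.
    """
    sched = econ.cost_schedule
    removal = sum(n * bracket_cost(d, sched.removal_brackets) for n, d in removals)
    pruning = sum(n / 4.0 * bracket_cost(d, sched.pruning_brackets) for n, d in living)
    injection = sum(n / 2.0 * injection_cost(d, sched.injection_per_cm)
                    for n, d in injected)
    planting = (plantings + replacement_deaths) * sched.planting_cost
    return CostBreakdown(
        removal=removal,
        pruning=pruning,
        injection=injection,
        planting=planting,
        year=year,
        pv_factor=discount_factor(year, econ),
    )


def population_ctla_pv(cohorts: Iterable, year: int, econ: EconParams) -> float:
    """Discounted trunk-formula value of a standing population."""
    nt = econ.cost_schedule.new_tree_unit_cost
    nominal = sum(
        c.count * ctla_value(c.dbh, nt, econ.ratings_for(c.species_class))
        for c in cohorts
    )
    return present_value(nominal, year, econ)
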