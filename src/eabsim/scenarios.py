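"""Declarative management scenarios and the annual event loop.

A :class:`ScenarioSpec` encodes when ash are injected, when and how fast
they are removed preemptively, whether dead ash are removed, and how
replacement non-ash trees are planted.  :func:`step_year` runs one year of
the deterministic event loop; :func:`run_scenario` runs a full horizon and
returns per-year records.

Event order within a year: grow, remove/kill, remove dead, plant, tally.
During an active preemptive-removal year ash mortality is suppressed —
scheduled removals subsume that year's deaths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

from .demography import (
    PRE_EXISTING,
    DemographyParams,
    TreeCohort,
    apply_annual_mortality,
    grow_dbh,
    survival_rate,
)
from .economics import EconParams, annual_cost, population_ctla_pv
from .errors import SequencingError, ValidationError
from .metrics import AnnualRecord, basal_printed, net_value

import math

__all__ = [
    "ScenarioSpec",
    "PopulationState",
    "RunResult",
    "builtin_scenarios",
    "get_scenario",
    "step_year",
    "run_scenario",
]

INJECT_NEVER = "never"
INJECT_WINDOW = "window"
INJECT_PERPETUITY = "perpetuity"

REPLANT_NONE = "none"
REPLANT_MATCH = "match_removals_same_site"
REPLANT_PROACTIVE = "proactive_alternative_site"


@dataclass(frozen=True)
class ScenarioSpec:
    """A declarative management rule-set for one scenario."""

    name: str
    inject_mode: str = INJECT_NEVER
    inject_start: int = 1
    inject_end: Optional[int] = None          # required for window mode
    preemptive_start: Optional[int] = None    # None = no preemptive removal
    preemptive_rate: int = 0                  # trees/yr
    remove_dead: bool = True
    replant_mode: str = REPLANT_NONE
    replant_rate: Optional[int] = None        # None = unbounded in match mode
    replant_start: int = 1
    replant_lag: int = 0                      # 0 = same year, 1 = following year
    replant_cap: Optional[int] = None         # cumulative plantings cap
    horizon: int = 20

    def validate(self) -> None:
        """Raise :class:`ValidationError` listing every offending field."""
        problems: List[str] = []
        if self.horizon < 1:
            problems.append("horizon must be >= 1")
        if self.inject_mode not in (INJECT_NEVER, INJECT_WINDOW, INJECT_PERPETUITY):
            problems.append(f"inject_mode {self.inject_mode!r} unknown")
        if self.inject_mode == INJECT_WINDOW:
            if self.inject_end is None:
                problems.append("inject_end required for windowed injection")
            elif not (1 <= self.inject_start <= self.inject_end):
                problems.append("injection window must satisfy 1 <= start <= end")
        if self.inject_mode == INJECT_PERPETUITY and self.preemptive_start is not None:
            problems.append("perpetual injection excludes preemptive removal")
        if self.preemptive_start is not None and self.preemptive_start < 1:
            problems.append("preemptive_start must be >= 1")
        if self.preemptive_rate < 0:
            problems.append("preemptive_rate must be >= 0")
        if self.replant_mode not in (REPLANT_NONE, REPLANT_MATCH, REPLANT_PROACTIVE):
            problems.append(f"replant_mode {self.replant_mode!r} unknown")
        if self.replant_mode == REPLANT_PROACTIVE and not self.replant_rate:
            problems.append("proactive replanting requires a replant_rate")
        if self.replant_rate is not None and self.replant_rate < 0:
            problems.append("replant_rate must be >= 0")
        if self.replant_lag not in (0, 1):
            problems.append("replant_lag must be 0 or 1")
        if self.replant_start < 1:
            problems.append("replant_start must be >= 1")
        if self.replant_cap is not None and self.replant_cap < 0:
            problems.append("replant_cap must be >= 0")
        if problems:
            raise ValidationError(
                f"invalid scenario {self.name!r}: " + "; ".join(problems))

    def is_injected(self, year: int) -> bool:
        if self.inject_mode == INJECT_PERPETUITY:
            return True
        if self.inject_mode == INJECT_WINDOW:
            return self.inject_start <= year <= self.inject_end
        return False

    def preemptive_active(self, year: int) -> bool:
        return (self.preemptive_start is not None
                and self.preemptive_rate > 0
                and year >= self.preemptive_start)


@dataclass(frozen=True)
class PopulationState:
    """Cohorts plus the simulation clock and rolling bookkeeping."""

    year: int
    cohorts: Tuple[TreeCohort, ...]
    total_planted: int = 0
    last_ash_losses: int = 0        # deaths + removals of ash, previous year
    cumulative_cost_pv: float = 0.0

    def ash_cohorts(self) -> List[TreeCohort]:
        return [c for c in self.cohorts if c.species_class == "ash"]

    def nonash_cohorts(self) -> List[TreeCohort]:
        return [c for c in self.cohorts if c.species_class == "nonash"]

    @property
    def ash_count(self) -> int:
        return sum(c.count for c in self.ash_cohorts())

    @property
    def nonash_count(self) -> int:
        return sum(c.count for c in self.nonash_cohorts())


@dataclass(frozen=True)
class RunResult:
    """A full deterministic run: the spec plus records for years 0..horizon."""

    spec: ScenarioSpec
    records: Tuple[AnnualRecord, ...]
    final_state: PopulationState

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame([r.to_dict() for r in self.records])


def _planting_request(spec: ScenarioSpec, state: PopulationState,
                      year: int, ash_losses: int) -> int:
    """Scheduled plantings this year before applying the cumulative cap."""
    if spec.replant_mode == REPLANT_MATCH:
        ref = ash_losses if spec.replant_lag == 0 else state.last_ash_losses
        return ref if spec.replant_rate is None else min(spec.replant_rate, ref)
    if spec.replant_mode == REPLANT_PROACTIVE and year >= spec.replant_start:
        return spec.replant_rate
    return 0


def step_year(
    state: PopulationState,
    spec: ScenarioSpec,
    params: DemographyParams,
    econ: Optional[EconParams] = None,
) -> Tuple[PopulationState, AnnualRecord]:
    """Advance the population by one year and emit its end-of-year record.

    Counts in the record are end-of-year states.  When ``econ`` is omitted
    the monetary fields of the record are zero.
    """
    if state.year >= spec.horizon:
        raise SequencingError(
            f"cannot step past horizon {spec.horizon} (at year {state.year})")
    year = state.year + 1

    # 1-2. Advance clock, grow every cohort.
    grown: List[TreeCohort] = []
    for c in state.cohorts:
        growth = params.ash_growth if c.species_class == "ash" else params.nonash_growth
        grown.append(replace(c, dbh=grow_dbh(c.dbh, growth)))
    ash = [c for c in grown if c.species_class == "ash"]
    nonash = [c for c in grown if c.species_class == "nonash"]
    ash_living = sum(c.count for c in ash)

    removals: List[Tuple[int, float]] = []   # (count, dbh) removed this year
    ash_deaths = 0
    preemptive_removed = 0
    new_ash: List[TreeCohort] = []
    injected_now = spec.is_injected(year)

    # 3. Preemptive removal (supersedes mortality) or mortality per cohort.
    if spec.preemptive_active(year) and ash_living > 0:
        to_remove = min(spec.preemptive_rate, ash_living)
        remaining = to_remove
        for c in ash:
            take = min(c.count, remaining)
            remaining -= take
            if take:
                removals.append((take, c.dbh))
            if c.count - take:
                new_ash.append(replace(c, count=c.count - take, injected=injected_now))
        preemptive_removed = to_remove
    else:
        for c in ash:
            rate = (params.injected_ash_mortality if injected_now
                    else params.noninjected_ash_mortality)
            survivors = apply_annual_mortality(c.count, rate)
            deaths = c.count - survivors
            ash_deaths += deaths
            # 4. Dead ash are removed (and stumped) the same year.
            if spec.remove_dead and deaths:
                removals.append((deaths, c.dbh))
            if survivors:
                new_ash.append(replace(c, count=survivors, injected=injected_now))

    # Non-ash cohorts age through the post-planting survival schedule.
    new_nonash: List[TreeCohort] = []
    nonash_deaths = 0
    replacement_deaths = 0  # post-warranty deaths, billed at planting cost
    for c in nonash:
        survival = (survival_rate(c.age_at(year), params) if c.is_planted
                    else 1.0 - params.natural_mortality)
        survivors = math.ceil(c.count * survival)
        deaths = c.count - survivors
        nonash_deaths += deaths
        age = c.age_at(year)
        if deaths and (age is None or age >= 3):
            replacement_deaths += deaths
        if survivors:
            new_nonash.append(replace(c, count=survivors))

    # 5. Plant replacement non-ash; first-year survival applies immediately
    # and the planting year counts one increment of growth.
    ash_losses = ash_deaths + preemptive_removed
    n_plant = _planting_request(spec, state, year, ash_losses)
    if spec.replant_cap is not None:
        n_plant = min(n_plant, max(spec.replant_cap - state.total_planted, 0))
    n_plant = max(n_plant, 0)
    if n_plant:
        first_year = math.ceil(n_plant * survival_rate(1, params))
        nonash_deaths += n_plant - first_year  # warranty deaths, free
        if first_year:
            new_nonash.append(TreeCohort(
                count=first_year,
                dbh=params.planting_dbh + params.nonash_growth,
                species_class="nonash",
                planting_year=year,
            ))

    # 6-7. Tally and record.
    cohorts = tuple(new_ash + new_nonash)
    ash_count = sum(c.count for c in new_ash)
    nonash_count = sum(c.count for c in new_nonash)
    injected_trees = sum(c.count for c in new_ash if c.injected)
    removed_total = sum(n for n, _ in removals)

    cost_fields = {}
    cumulative_cost_pv = state.cumulative_cost_pv
    if econ is not None:
        breakdown = annual_cost(
            removals=removals,
            living=[(c.count, c.dbh) for c in cohorts],
            injected=[(c.count, c.dbh) for c in new_ash if c.injected],
            plantings=n_plant,
            replacement_deaths=replacement_deaths,
            year=year,
            econ=econ,
        )
        cumulative_cost_pv += breakdown.total_pv
        ctla_pv = population_ctla_pv(cohorts, year, econ)
        cost_fields = dict(
            cost_removal=breakdown.removal,
            cost_pruning=breakdown.pruning,
            cost_injection=breakdown.injection,
            cost_planting=breakdown.planting,
            annual_cost_nominal=breakdown.total_nominal,
            annual_cost_pv=breakdown.total_pv,
            cumulative_cost_pv=cumulative_cost_pv,
            ctla_value_pv=ctla_pv,
            net_value_pv=net_value(ctla_pv, cumulative_cost_pv),
        )

    record = AnnualRecord(
        year=year,
        ash_count=ash_count,
        nonash_count=nonash_count,
        ash_basal=basal_printed(new_ash),
        nonash_basal=basal_printed(new_nonash),
        ash_deaths=ash_deaths,
        nonash_deaths=nonash_deaths,
        removals=removed_total,
        plantings=n_plant,
        injected_trees=injected_trees,
        **cost_fields,
    )
    new_state = PopulationState(
        year=year,
        cohorts=cohorts,
        total_planted=state.total_planted + n_plant,
        last_ash_losses=ash_losses,
        cumulative_cost_pv=cumulative_cost_pv,
    )
    return new_state, record


def initial_state(params: DemographyParams) -> PopulationState:
    """Year-0 state: a single pre-existing ash cohort."""
    cohort = TreeCohort(
        count=params.initial_ash_count,
        dbh=params.initial_ash_dbh,
        species_class="ash",
        injected=False,
        planting_year=PRE_EXISTING,
    )
    return PopulationState(year=0, cohorts=(cohort,))


def run_scenario(
    spec: ScenarioSpec,
    params: Optional[DemographyParams] = None,
    econ: Optional[EconParams] = None,
) -> RunResult:
    """Run one scenario for its full horizon.

    Deterministic: identical inputs give identical outputs bit-for-bit.
    The first record is the Year-0 initial state.
    """
    params = params or DemographyParams()
    spec.validate()
    state = initial_state(params)
    year0_ctla = (population_ctla_pv(state.cohorts, 0, econ)
                  if econ is not None else 0.0)
    records = [AnnualRecord(
        year=0,
        ash_count=state.ash_count,
        nonash_count=state.nonash_count,
        ash_basal=basal_printed(state.ash_cohorts()),
        nonash_basal=basal_printed(state.nonash_cohorts()),
        ctla_value_pv=year0_ctla,
        net_value_pv=year0_ctla,
    )]
    for _ in range(spec.horizon):
        state, record = step_year(state, spec, params, econ)
        records.append(record)
    return RunResult(spec=spec, records=tuple(records), final_state=state)


def builtin_scenarios(horizon: int = 20) -> List[ScenarioSpec]:
    """The seven built-in management scenarios.

    Defaults: injections in windowed scenarios run Years 1-5; preemptive
    removals run at 400 trees/yr, starting Year 1 when removal leads the
    program and Year 6 when it follows the injection window; replanting
    matches ash losses (same year, or following year for the
    remove-then-replant scenario) or plants proactively at 400/yr capped at
    a 1:1 replacement of the initial 1,490 ash.
    """
    specs = [
        ScenarioSpec(
            name="Remove Dead Ash Only (Control)",
            horizon=horizon,
        ),
        ScenarioSpec(
            name="Remove Dead Ash then Replant",
            replant_mode=REPLANT_MATCH,
            replant_lag=1,
            horizon=horizon,
        ),
        ScenarioSpec(
            name="Preemptive Removal then Replant",
            preemptive_start=1,
            preemptive_rate=400,
            replant_mode=REPLANT_MATCH,
            replant_rate=400,
            replant_lag=0,
            horizon=horizon,
        ),
        ScenarioSpec(
            name="Replant, Inject, then Preemptive Removal",
            inject_mode=INJECT_WINDOW,
            inject_start=1,
            inject_end=5,
            preemptive_start=6,
            preemptive_rate=400,
            replant_mode=REPLANT_PROACTIVE,
            replant_rate=400,
            replant_start=1,
            replant_cap=1490,
            horizon=horizon,
        ),
        ScenarioSpec(
            name="Inject, Preemptive Removal, and Replant",
            inject_mode=INJECT_WINDOW,
            inject_start=1,
            inject_end=5,
            preemptive_start=6,
            preemptive_rate=400,
            replant_mode=REPLANT_MATCH,
            replant_rate=400,
            replant_lag=0,
            horizon=horizon,
        ),
        ScenarioSpec(
            name="Injection in Perpetuity",
            inject_mode=INJECT_PERPETUITY,
            horizon=horizon,
        ),
        ScenarioSpec(
            name="Injection in Perpetuity with Replanting",
            inject_mode=INJECT_PERPETUITY,
            replant_mode=REPLANT_MATCH,
            replant_lag=0,
            horizon=horizon,
        ),
    ]
    for s in specs:
        s.validate()
    return specs


def get_scenario(name: str, horizon: int = 20) -> ScenarioSpec:
    """Look up a built-in scenario by (case-insensitive) name."""
    wanted = name.strip().lower()
    for spec in builtin_scenarios(horizon):
        if spec.name.lower() == wanted:
            return spec
    known = ", ".join(s.name for s in builtin_scenarios(horizon))
    raise ValidationError(f"unknown scenario {name!r}; known scenarios: {known}")
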