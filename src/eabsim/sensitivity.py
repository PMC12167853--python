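"""Grid sweeps over the four management decisions and per-objective optima.

The four decisions are: the year injections end, the year preemptive
removals start, the annual removal rate, and the annual planting rate.
Sweeps are one-at-a-time by default (each decision varied with the others
held at the base scenario's values); a full factorial crossing is also
available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .demography import DemographyParams
from .economics import EconParams
from .errors import ValidationError
from .scenarios import (
    INJECT_WINDOW,
    REPLANT_NONE,
    ScenarioSpec,
    run_scenario,
)

__all__ = ["SweepGrid", "run_sweep", "optima_summary", "SWEEP_OBJECTIVES"]

DECISIONS = ("injection_end", "removal_start", "removal_rate", "planting_rate")

#: Objective name -> (sweep-table column, maximize?)
SWEEP_OBJECTIVES: Dict[str, Tuple[str, bool]] = {
    "trees": ("total_count", True),
    "basal": ("total_basal", True),
    "ash": ("ash_count", True),
    "cost": ("cumulative_cost_pv", False),
    "ctla": ("ctla_value_pv", True),
    "net_value": ("net_value_pv", True),
}


@dataclass(frozen=True)
class SweepGrid:
    """Grid of decision values to sweep around a base scenario.

    Decision lists left as None are not varied.  ``mode`` is
    ``"one_at_a_time"`` (default) or ``"factorial"``.
    """

    base_scenario: ScenarioSpec
    injection_end_years: Optional[Sequence[int]] = None
    removal_start_years: Optional[Sequence[int]] = None
    removal_rates: Optional[Sequence[int]] = None
    planting_rates: Optional[Sequence[int]] = None
    mode: str = "one_at_a_time"

    def varied(self) -> Dict[str, Sequence[int]]:
        out = {}
        for name, values in (
            ("injection_end", self.injection_end_years),
            ("removal_start", self.removal_start_years),
            ("removal_rate", self.removal_rates),
            ("planting_rate", self.planting_rates),
        ):
            if values is not None:
                vals = list(values)
                if not vals:
                    raise ValidationError(f"{name}: empty value list")
                out[name] = vals
        return out

    def validate(self) -> None:
        spec = self.base_scenario
        spec.validate()
        if self.mode not in ("one_at_a_time", "factorial"):
            raise ValidationError(f"unknown sweep mode {self.mode!r}")
        varied = self.varied()
        if not varied:
            raise ValidationError("sweep grid varies no decision")
        if "injection_end" in varied and spec.inject_mode != INJECT_WINDOW:
            raise ValidationError(
                "base scenario has no injection window to vary")
        if ("removal_start" in varied or "removal_rate" in varied) \
                and spec.preemptive_start is None:
            raise ValidationError(
                "base scenario has no preemptive removal to vary")
        if "planting_rate" in varied and spec.replant_mode == REPLANT_NONE:
            raise ValidationError("base scenario has no replanting to vary")


def apply_decisions(
    spec: ScenarioSpec,
    injection_end: Optional[int] = None,
    removal_start: Optional[int] = None,
    removal_rate: Optional[int] = None,
    planting_rate: Optional[int] = None,
) -> ScenarioSpec:
    """Return the base spec with the given decisions overridden.

    When the base couples removal start to the injection window (start ==
    inject_end + 1) and only the injection end is varied, the coupling is
    preserved: removals begin the year after injections cease.
    """
    changes: dict = {}
    if injection_end is not None:
        changes["inject_end"] = injection_end
        coupled = (spec.preemptive_start is not None
                   and spec.inject_end is not None
                   and spec.preemptive_start == spec.inject_end + 1)
        if coupled and removal_start is None:
            changes["preemptive_start"] = injection_end + 1
    if removal_start is not None:
        changes["preemptive_start"] = removal_start
    if removal_rate is not None:
        changes["preemptive_rate"] = removal_rate
    if planting_rate is not None:
        changes["replant_rate"] = planting_rate
    return replace(spec, **changes)


def _summary_row(point: Dict[str, Optional[int]], result) -> dict:
    rec = result.records[-1]
    row = {d: point.get(d) for d in DECISIONS}
    row.update({
        "scenario": result.spec.name,
        "year": rec.year,
        "ash_count": rec.ash_count,
        "nonash_count": rec.nonash_count,
        "total_count": rec.total_count,
        "ash_basal": rec.ash_basal,
        "nonash_basal": rec.nonash_basal,
        "total_basal": rec.total_basal,
        "cumulative_cost_pv": rec.cumulative_cost_pv,
        "ctla_value_pv": rec.ctla_value_pv,
        "net_value_pv": rec.net_value_pv,
    })
    return row


def _grid_points(grid: SweepGrid) -> List[Dict[str, int]]:
    varied = grid.varied()
    if grid.mode == "factorial":
        names = list(varied)
        return [dict(zip(names, combo))
                for combo in itertools.product(*(varied[n] for n in names))]
    points: List[Dict[str, int]] = []
    for name, values in varied.items():
        points.extend({name: v} for v in values)
    return points


def run_sweep(
    grid: SweepGrid,
    params: Optional[DemographyParams] = None,
    econ: Optional[EconParams] = None,
) -> pd.DataFrame:
    """Run the sweep and return one final-year summary row per grid point.

    Deterministic; the row count equals the grid cardinality and the output
    is invariant (up to row order metadata) to permutations of the value
    lists.
    """
    grid.validate()
    params = params or DemographyParams()
    rows = []
    for point in _grid_points(grid):
        spec = apply_decisions(grid.base_scenario, **{
            "injection_end": point.get("injection_end"),
            "removal_start": point.get("removal_start"),
            "removal_rate": point.get("removal_rate"),
            "planting_rate": point.get("planting_rate"),
        })
        result = run_scenario(spec, params, econ)
        rows.append(_summary_row(point, result))
    return pd.DataFrame(rows)


def optima_summary(table: pd.DataFrame, objective: str) -> pd.DataFrame:
    """Rows of the sweep table achieving the objective's optimum (ties kept)."""
    if table.empty:
        raise ValidationError("empty sweep table")
    if objective not in SWEEP_OBJECTIVES:
        raise ValidationError(
            f"unknown objective {objective!r}; known: {sorted(SWEEP_OBJECTIVES)}")
    column, maximize = SWEEP_OBJECTIVES[objective]
    best = table[column].max() if maximize else table[column].min()
    return table[table[column] == best].copy()
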