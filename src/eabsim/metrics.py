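"""Derived outputs: basal area in printed units, net value, normalized costs,
ratios to a control series, and objective-based scenario rankings."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ParameterError, ValidationError

__all__ = [
    "AnnualRecord",
    "OBJECTIVES",
    "basal_printed",
    "net_value",
    "normalized_costs",
    "ratio_to_control",
    "objective_rankings",
]

#: Objective name -> (record attribute at the final year, maximize?)
OBJECTIVES: Dict[str, Tuple[str, bool]] = {
    "preserve_trees": ("total_count", True),
    "preserve_basal": ("total_basal", True),
    "preserve_ash": ("ash_count", True),
    "cost_reduction": ("cumulative_cost_pv", False),
    "value_maximization": ("net_value_pv", True),
}


@dataclass(frozen=True)
class AnnualRecord:
    """End-of-year snapshot of one simulated year.

    Monetary fields are zero when a run is executed without economic
    parameters.  Basal areas are in printed units: total trunk
    cross-sectional area in cm^2 divided by 1,000.
    """

    year: int
    ash_count: int
    nonash_count: int
    ash_basal: float
    nonash_basal: float
    ash_deaths: int = 0
    nonash_deaths: int = 0
    removals: int = 0
    plantings: int = 0
    injected_trees: int = 0
    cost_removal: float = 0.0
    cost_pruning: float = 0.0
    cost_injection: float = 0.0
    cost_planting: float = 0.0
    annual_cost_nominal: float = 0.0
    annual_cost_pv: float = 0.0
    cumulative_cost_pv: float = 0.0
    ctla_value_pv: float = 0.0
    net_value_pv: float = 0.0

    @property
    def total_count(self) -> int:
        return self.ash_count + self.nonash_count

    @property
    def total_basal(self) -> float:
        return self.ash_basal + self.nonash_basal

    def to_dict(self) -> dict:
        d = asdict(self)
        d["total_count"] = self.total_count
        d["total_basal"] = self.total_basal
        return d


def basal_printed(cohorts: Iterable) -> float:
    """Total trunk cross-sectional area of the cohorts, in cm^2 / 1000.

    Accepts any iterable of objects with ``count`` and ``dbh`` attributes,
    or of ``(count, dbh)`` pairs.
    """
    total = 0.0
    for c in cohorts:
        try:
            count, dbh = c.count, c.dbh
        except AttributeError:
            count, dbh = c
        total += count * math.pi * (dbh / 2.0) ** 2
    return total / 1000.0


def net_value(ctla_pv: float, cumulative_cost_pv: float) -> float:
    """Discounted appraisal value of the standing trees minus cumulative cost."""
    return ctla_pv - cumulative_cost_pv


def normalized_costs(record: AnnualRecord) -> Tuple[float, float]:
    """Discounted annual cost per tree and per printed basal unit.

    Zero denominators yield NaN (rendered as missing downstream), not an
    exception.
    """
    per_tree = (record.annual_cost_pv / record.total_count
                if record.total_count > 0 else math.nan)
    per_basal = (record.annual_cost_pv / record.total_basal
                 if record.total_basal > 0 else math.nan)
    return per_tree, per_basal


def ratio_to_control(series: Sequence[float], control_series: Sequence[float]) -> np.ndarray:
    """Elementwise ratio of a cost series to the control's; NaN where the
    control is zero."""
    a = np.asarray(series, dtype=float)
    b = np.asarray(control_series, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(
            f"series lengths differ: {a.shape} vs {b.shape}")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(b != 0, a / np.where(b != 0, b, 1.0), np.nan)
    return out


def _final_record(result) -> AnnualRecord:
    return result.records[-1]


def objective_rankings(run_results: Sequence) -> "pd.DataFrame":
    """Rank scenario runs under each management objective.

    For every objective in :data:`OBJECTIVES` the runs are ordered by their
    final-year criterion (best first).  Ties are broken by lower cumulative
    discounted cost, then scenario name.  All runs must share a horizon.
    """
    import pandas as pd

    if len(run_results) < 1:
        raise ValidationError("objective_rankings requires at least one run")
    horizons = {r.spec.horizon for r in run_results}
    if len(horizons) != 1:
        raise ValidationError(f"mixed horizons in ranking input: {sorted(horizons)}")

    rows = []
    for objective, (attr, maximize) in OBJECTIVES.items():
        keyed = []
        for r in run_results:
            rec = _final_record(r)
            value = getattr(rec, attr)
            primary = -value if maximize else value
            keyed.append((primary, rec.cumulative_cost_pv, r.spec.name, value, r))
        keyed.sort(key=lambda k: (k[0], k[1], k[2]))
        best = keyed[0][0]
        for rank, (primary, _, name, value, _) in enumerate(keyed, start=1):
            rows.append({
                "objective": objective,
                "rank": rank,
                "scenario": name,
                "criterion": value,
                "tied_for_best": primary == best,
            })
    return pd.DataFrame(rows)
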