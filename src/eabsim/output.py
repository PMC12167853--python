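"""Tabular (CSV) and manifest (JSON) output writers, plus optional plots."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .config import RunConfig, config_to_dict
from .errors import ValidationError
from .metrics import normalized_costs
from .scenarios import RunResult

__all__ = ["counts_basal_frame", "economics_frame", "write_outputs", "write_plots"]


def counts_basal_frame(
    results: Sequence[RunResult],
    report_years: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Long-to-wide table: scenario x species-group x metric, year columns.

    Species groups are ash, nonash and all; metrics are tree count and
    printed basal area.
    """
    if not results:
        raise ValidationError("no results to write")
    rows = []
    for result in results:
        years = [r.year for r in result.records]
        wanted = list(report_years) if report_years is not None else years
        missing = set(wanted) - set(years)
        if missing:
            raise ValidationError(f"report years {sorted(missing)} outside run")
        by_year = {r.year: r for r in result.records}
        groups = {
            ("ash", "count"): lambda r: r.ash_count,
            ("ash", "basal"): lambda r: r.ash_basal,
            ("nonash", "count"): lambda r: r.nonash_count,
            ("nonash", "basal"): lambda r: r.nonash_basal,
            ("all", "count"): lambda r: r.total_count,
            ("all", "basal"): lambda r: r.total_basal,
        }
        for (species, metric), getter in groups.items():
            row: Dict[str, object] = {
                "scenario": result.spec.name,
                "species": species,
                "metric": metric,
            }
            for y in wanted:
                row[f"year_{y}"] = getter(by_year[y])
            rows.append(row)
    return pd.DataFrame(rows)


def economics_frame(results: Sequence[RunResult]) -> pd.DataFrame:
    """Per-scenario, per-year monetary series with normalized-cost columns."""
    if not results:
        raise ValidationError("no results to write")
    rows = []
    for result in results:
        for rec in result.records:
            per_tree, per_basal = normalized_costs(rec)
            row = rec.to_dict()
            row["scenario"] = result.spec.name
            row["cost_per_tree_pv"] = per_tree
            row["cost_per_basal_pv"] = per_basal
            rows.append(row)
    frame = pd.DataFrame(rows)
    cols = ["scenario"] + [c for c in frame.columns if c != "scenario"]
    return frame[cols]


def write_outputs(
    results: Sequence[RunResult],
    outdir: Union[str, Path],
    config: Optional[RunConfig] = None,
    report_years: Optional[Sequence[int]] = None,
    sweep: Optional[pd.DataFrame] = None,
) -> Dict[str, Path]:
    """Write counts_basal.csv, economics.csv, optional sweep.csv, and a
    manifest of all resolved parameters.  Returns the written paths."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValidationError(f"cannot create output directory {outdir}: {exc}") from exc

    paths: Dict[str, Path] = {}
    cb = counts_basal_frame(results, report_years)
    paths["counts_basal"] = outdir / "counts_basal.csv"
    cb.to_csv(paths["counts_basal"], index=False, lineterminator="\r\n")

    econ = economics_frame(results)
    paths["economics"] = outdir / "economics.csv"
    econ.to_csv(paths["economics"], index=False, lineterminator="\r\n")

    if sweep is not None:
        paths["sweep"] = outdir / "sweep.csv"
        sweep.to_csv(paths["sweep"], index=False, lineterminator="\r\n")

    if config is not None:
        paths["manifest"] = outdir / "manifest.json"
        paths["manifest"].write_text(
            json.dumps(config_to_dict(config), indent=2, sort_keys=True) + "\n")
    return paths


def write_plots(results: Sequence[RunResult], outdir: Union[str, Path]) -> List[Path]:
    """Optional PNG plots: counts/basal trajectories and discounted costs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    fig, axes = plt.subplots(2, 2, figsize=(12, 8), sharex=True)
    panels = [
        ("total_count", "Total trees"),
        ("total_basal", "Total basal (printed units)"),
        ("annual_cost_pv", "Discounted annual cost ($)"),
        ("cumulative_cost_pv", "Discounted cumulative cost ($)"),
    ]
    for ax, (attr, title) in zip(axes.flat, panels):
        for result in results:
            years = [r.year for r in result.records]
            values = [getattr(r, attr) if attr in r.to_dict() else r.to_dict()[attr]
                      for r in result.records]
            ax.plot(years, values, label=result.spec.name)
        ax.set_title(title)
        ax.set_xlabel("Year")
    axes.flat[0].legend(fontsize=6)
    fig.tight_layout()
    path = outdir / "overview.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written
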