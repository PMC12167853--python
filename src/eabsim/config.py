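"""Configuration loading, defaults, serialization, and fixture generation.

The configuration file is YAML (JSON is a subset and is accepted).  Every
field has a package default, so an empty file yields the reference
parameterization.  Open-ended cost brackets are written with a null upper
bound and parsed to +inf.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Union

import numpy as np
import yaml

from .demography import DemographyParams
from .economics import CostSchedule, EconParams, RatingSet
from .errors import ConfigError, ValidationError
from .scenarios import (
    INJECT_NEVER,
    INJECT_PERPETUITY,
    INJECT_WINDOW,
    REPLANT_MATCH,
    REPLANT_NONE,
    REPLANT_PROACTIVE,
    ScenarioSpec,
    builtin_scenarios,
    get_scenario,
)

__all__ = [
    "RunConfig",
    "default_config",
    "load_config",
    "config_from_dict",
    "config_to_dict",
    "fixture_generator",
]


@dataclass(frozen=True)
class RunConfig:
    demography: DemographyParams
    econ: EconParams
    scenarios: tuple
    horizon: int = 20
    output_dir: str = "out"
    discount_override: Optional[float] = None

    def effective_econ(self) -> EconParams:
        if self.discount_override is None:
            return self.econ
        return dataclasses.replace(self.econ, discount=self.discount_override)


def default_config(horizon: int = 20) -> RunConfig:
    return RunConfig(
        demography=DemographyParams(),
        econ=EconParams(),
        scenarios=tuple(builtin_scenarios(horizon)),
        horizon=horizon,
    )


def _require_mapping(obj: Any, key: str) -> dict:
    if obj is None:
        return {}
    if not isinstance(obj, dict):
        raise ConfigError(f"{key}: expected a mapping, got {type(obj).__name__}")
    return obj


def _check_keys(data: dict, allowed: set, context: str) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ValidationError(
            f"{context}: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}")


def _parse_brackets(raw, key: str):
    if raw is None:
        return None
    out = []
    for pair in raw:
        upper, cost = pair
        out.append((math.inf if upper is None else float(upper), float(cost)))
    return tuple(out)


def _parse_ratings(raw, key: str) -> Optional[RatingSet]:
    if raw is None:
        return None
    raw = _require_mapping(raw, key)
    _check_keys(raw, {"condition", "functional", "external"}, key)
    try:
        return RatingSet(raw["condition"], raw["functional"], raw["external"])
    except KeyError as exc:
        raise ValidationError(f"{key}: missing rating {exc.args[0]!r}") from None


def _parse_demography(raw) -> DemographyParams:
    raw = _require_mapping(raw, "demography")
    fields = {f.name for f in dataclasses.fields(DemographyParams)}
    _check_keys(raw, fields, "demography")
    kwargs = dict(raw)
    if "warranty_survival" in kwargs:
        kwargs["warranty_survival"] = tuple(
            (int(y), float(s)) for y, s in kwargs["warranty_survival"])
    return DemographyParams(**kwargs)


def _parse_econ(raw) -> EconParams:
    raw = _require_mapping(raw, "econ")
    _check_keys(raw, {"inflation", "discount", "ash_ratings", "nonash_ratings",
                      "cost_schedule"}, "econ")
    kwargs: Dict[str, Any] = {}
    for key in ("inflation", "discount"):
        if key in raw:
            kwargs[key] = float(raw[key])
    for key in ("ash_ratings", "nonash_ratings"):
        ratings = _parse_ratings(raw.get(key), f"econ.{key}")
        if ratings is not None:
            kwargs[key] = ratings
    sched_raw = _require_mapping(raw.get("cost_schedule"), "econ.cost_schedule")
    if sched_raw:
        sched_fields = {f.name for f in dataclasses.fields(CostSchedule)}
        _check_keys(sched_raw, sched_fields, "econ.cost_schedule")
        sched_kwargs = dict(sched_raw)
        for key in ("removal_brackets", "pruning_brackets"):
            parsed = _parse_brackets(sched_kwargs.get(key), f"econ.cost_schedule.{key}")
            if parsed is not None:
                sched_kwargs[key] = parsed
        kwargs["cost_schedule"] = CostSchedule(**sched_kwargs)
    return EconParams(**kwargs)


def _parse_scenario(raw, horizon: int) -> ScenarioSpec:
    if isinstance(raw, str):
        return get_scenario(raw, horizon)
    raw = _require_mapping(raw, "scenarios[]")
    fields = {f.name for f in dataclasses.fields(ScenarioSpec)}
    _check_keys(raw, fields, f"scenario {raw.get('name', '?')!r}")
    if "name" not in raw:
        raise ValidationError("scenario mapping requires a 'name'")
    kwargs = dict(raw)
    kwargs.setdefault("horizon", horizon)
    spec = ScenarioSpec(**kwargs)
    spec.validate()
    return spec


def config_from_dict(data: Optional[dict]) -> RunConfig:
    """Build a validated config, filling package defaults for omitted keys."""
    data = _require_mapping(data, "config")
    _check_keys(data, {"demography", "econ", "scenarios", "horizon",
                       "output_dir", "discount_override"}, "config")
    horizon = int(data.get("horizon", 20))
    if horizon < 1:
        raise ValidationError("horizon: must be >= 1")
    demography = _parse_demography(data.get("demography"))
    econ = _parse_econ(data.get("econ"))
    raw_scenarios = data.get("scenarios")
    if raw_scenarios is None:
        scenarios = tuple(builtin_scenarios(horizon))
    else:
        scenarios = tuple(_parse_scenario(s, horizon) for s in raw_scenarios)
    override = data.get("discount_override")
    return RunConfig(
        demography=demography,
        econ=econ,
        scenarios=scenarios,
        horizon=horizon,
        output_dir=str(data.get("output_dir", "out")),
        discount_override=None if override is None else float(override),
    )


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML/JSON configuration file.

    An empty file yields the full default configuration.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    return config_from_dict(data)


def _brackets_to_jsonable(brackets):
    return [[None if math.isinf(u) else u, c] for u, c in brackets]


def config_to_dict(config: RunConfig) -> dict:
    """Serialize a config losslessly to plain JSON/YAML-safe types."""
    demo = dataclasses.asdict(config.demography)
    demo["warranty_survival"] = [list(p) for p in demo["warranty_survival"]]
    econ = {
        "inflation": config.econ.inflation,
        "discount": config.econ.discount,
        "ash_ratings": dataclasses.asdict(config.econ.ash_ratings),
        "nonash_ratings": dataclasses.asdict(config.econ.nonash_ratings),
        "cost_schedule": {
            "removal_brackets": _brackets_to_jsonable(
                config.econ.cost_schedule.removal_brackets),
            "pruning_brackets": _brackets_to_jsonable(
                config.econ.cost_schedule.pruning_brackets),
            "injection_per_cm": config.econ.cost_schedule.injection_per_cm,
            "planting_cost": config.econ.cost_schedule.planting_cost,
            "new_tree_unit_cost": config.econ.cost_schedule.new_tree_unit_cost,
        },
    }
    return {
        "demography": demo,
        "econ": econ,
        "scenarios": [dataclasses.asdict(s) for s in config.scenarios],
        "horizon": config.horizon,
        "output_dir": config.output_dir,
        "discount_override": config.discount_override,
    }


def _random_scenario(rng: np.random.Generator, horizon: int) -> ScenarioSpec:
    inject_mode = rng.choice([INJECT_NEVER, INJECT_WINDOW, INJECT_PERPETUITY])
    kwargs: Dict[str, Any] = {"name": f"random-{rng.integers(1 << 30)}",
                              "inject_mode": str(inject_mode), "horizon": horizon}
    if inject_mode == INJECT_WINDOW:
        start = int(rng.integers(1, horizon + 1))
        kwargs["inject_start"] = start
        kwargs["inject_end"] = int(rng.integers(start, horizon + 1))
    if inject_mode != INJECT_PERPETUITY and rng.random() < 0.5:
        kwargs["preemptive_start"] = int(rng.integers(1, horizon + 1))
        kwargs["preemptive_rate"] = int(rng.integers(0, 1001))
    replant_mode = str(rng.choice([REPLANT_NONE, REPLANT_MATCH, REPLANT_PROACTIVE]))
    kwargs["replant_mode"] = replant_mode
    if replant_mode != REPLANT_NONE:
        kwargs["replant_rate"] = int(rng.integers(1, 1001))
        kwargs["replant_start"] = int(rng.integers(1, horizon + 1))
        kwargs["replant_lag"] = int(rng.integers(0, 2))
        if rng.random() < 0.5:
            kwargs["replant_cap"] = int(rng.integers(0, 5001))
    return ScenarioSpec(**kwargs)


def fixture_generator(seed: int) -> RunConfig:
    """A random, schema-valid configuration, reproducible from the seed.

    Used as the synthetic-input source for property tests: rates are drawn
    in [0, 1], counts in [0, 10^4], brackets are sorted, and the horizon is
    in [1, 40].
    """
    rng = np.random.default_rng(seed)
    horizon = int(rng.integers(1, 41))
    warranty = tuple((y, float(rng.uniform(0.5, 1.0))) for y in range(1, 5))
    demography = DemographyParams(
        natural_mortality=float(rng.uniform(0, 0.2)),
        injected_ash_mortality=float(rng.uniform(0, 1)),
        noninjected_ash_mortality=float(rng.uniform(0, 1)),
        ash_growth=float(rng.uniform(0, 2)),
        nonash_growth=float(rng.uniform(0, 2)),
        warranty_survival=warranty,
        planting_dbh=float(rng.uniform(1, 20)),
        initial_ash_count=int(rng.integers(0, 10_001)),
        initial_ash_dbh=float(rng.uniform(1, 120)),
    )
    n_brackets = int(rng.integers(2, 8))
    uppers = np.sort(rng.uniform(5, 150, size=n_brackets - 1))
    removal = tuple(zip(uppers, np.sort(rng.uniform(10, 5000, size=n_brackets - 1))))
    pruning = tuple(zip(uppers, np.sort(rng.uniform(10, 1000, size=n_brackets - 1))))
    schedule = CostSchedule(
        removal_brackets=removal + ((math.inf, 6000.0),),
        pruning_brackets=pruning + ((math.inf, 1000.0),),
        injection_per_cm=float(rng.uniform(0, 10)),
        planting_cost=float(rng.uniform(0, 2000)),
        new_tree_unit_cost=float(rng.uniform(0, 10)),
    )
    econ = EconParams(
        inflation=float(rng.uniform(0, 0.1)),
        discount=float(rng.uniform(0, 0.1)),
        ash_ratings=RatingSet(*(float(rng.uniform(0, 1)) for _ in range(3))),
        nonash_ratings=RatingSet(*(float(rng.uniform(0, 1)) for _ in range(3))),
        cost_schedule=schedule,
    )
    n_scenarios = int(rng.integers(1, 4))
    scenarios = tuple(_random_scenario(rng, horizon) for _ in range(n_scenarios))
    for s in scenarios:
        s.validate()
    return RunConfig(
        demography=demography,
        econ=econ,
        scenarios=scenarios,
        horizon=horizon,
    )
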