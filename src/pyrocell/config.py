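"""Run configuration: strict YAML schema and forward-dating of inputs.

A run config resolves everything a simulation needs: where the inputs
come from (a scenario name or a directory of rasters), the model
parameter overrides, the forecast horizon, and the subcommand-specific
blocks (Monte Carlo ensemble size and perturbations, validation
reference, interactive forward-dating).  Unknown keys are errors with a
closest-match suggestion, so typos never silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
import difflib
from dataclasses import dataclass, field
from typing import Any, Dict, Optional, Sequence, Tuple

import numpy as np
import yaml

from .landscape import Landscape
from .montecarlo import PerturbationSpec, VariablePerturbation
from .params import ModelParams

__all__ = ["RunConfig", "load_config", "forward_date_inputs"]

#: default per-day linear trends applied when forward-dating inputs:
#: fuel cures (accumulates dry biomass) and vegetation dries slightly.
DEFAULT_FUEL_TREND = (0.005, 0.0)       # (per-day slope, intercept term)
DEFAULT_MOISTURE_TREND = (-0.01, 0.0)

MAX_FORWARD_DAYS = 20


@dataclass
class MonteCarloConfig:
    n_runs: int = 100
    wind_speed_sd: float = 0.0
    wind_direction_sd: float = 0.0
    fuel_sd: float = 0.0
    moisture_sd: float = 0.0
    ignition_rate: Optional[float] = None

    def to_spec(self) -> PerturbationSpec:
        return PerturbationSpec(
            wind_speed=VariablePerturbation(self.wind_speed_sd,
                                            bounds=(0.0, None)),
            wind_direction=VariablePerturbation(self.wind_direction_sd),
            fuel=VariablePerturbation(self.fuel_sd, bounds=(0.0, 1.0)),
            moisture=VariablePerturbation(self.moisture_sd,
                                          bounds=(0.0, 1.0)),
            ignition_rate=self.ignition_rate,
        )


@dataclass
class InteractiveConfig:
    """Local interactive block: user ignition points + forward dating."""

    ignition_cells: Tuple[Tuple[int, int], ...] = ()
    days_ahead: int = 0
    fuel_trend: Tuple[float, ...] = DEFAULT_FUEL_TREND
    moisture_trend: Tuple[float, ...] = DEFAULT_MOISTURE_TREND

    def __post_init__(self) -> None:
        if not (0 <= self.days_ahead <= MAX_FORWARD_DAYS):
            raise ValueError(
                f"days_ahead must lie in [0, {MAX_FORWARD_DAYS}] "
                f"(inputs can only be forward-dated up to "
                f"{MAX_FORWARD_DAYS} days), got {self.days_ahead}"
            )


@dataclass
class RunConfig:
    """Fully resolved configuration of one command invocation."""

    scenario: Optional[str] = None
    scenario_overrides: Dict[str, Any] = field(default_factory=dict)
    input_dir: Optional[str] = None
    horizon_hours: float = 8.0
    output_dir: str = "."
    params: ModelParams = field(default_factory=ModelParams)
    montecarlo: MonteCarloConfig = field(default_factory=MonteCarloConfig)
    interactive: Optional[InteractiveConfig] = None
    reference_scar: Optional[str] = None

    def __post_init__(self) -> None:
        if self.horizon_hours <= 0:
            raise ValueError(f"horizon_hours must be > 0, "
                             f"got {self.horizon_hours}")
        if self.scenario is None and self.input_dir is None:
            raise ValueError("config must name a scenario or an input_dir")


def _check_keys(mapping: Dict[str, Any], allowed: Sequence[str],
                context: str) -> None:
    for key in mapping:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown {context} key {key!r}{suggestion}")


_TOP_KEYS = ("scenario", "scenario_overrides", "input_dir", "horizon_hours",
             "output_dir", "params", "montecarlo", "interactive",
             "reference_scar")
_PARAM_KEYS = tuple(f.name for f in dataclasses.fields(ModelParams))
_MC_KEYS = tuple(f.name for f in dataclasses.fields(MonteCarloConfig))
_LOCAL_KEYS = tuple(f.name for f in dataclasses.fields(InteractiveConfig))


def load_config(path: str) -> RunConfig:
    """Load and validate a YAML run config.

    Every key is checked against the schema; unknown keys raise with a
    nearest-match suggestion and missing required keys are named.
    """
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    params_raw = raw.get("params") or {}
    _check_keys(params_raw, _PARAM_KEYS, "params")
    if "moisture_poly" in params_raw:
        params_raw["moisture_poly"] = tuple(params_raw["moisture_poly"])
    params = ModelParams(**params_raw)

    mc_raw = raw.get("montecarlo") or {}
    _check_keys(mc_raw, _MC_KEYS, "montecarlo")
    montecarlo = MonteCarloConfig(**mc_raw)

    interactive = None
    if "interactive" in raw and raw["interactive"] is not None:
        local_raw = dict(raw["interactive"])
        _check_keys(local_raw, _LOCAL_KEYS, "interactive")
        if "ignition_cells" in local_raw:
            local_raw["ignition_cells"] = tuple(
                tuple(cell) for cell in local_raw["ignition_cells"])
        for key in ("fuel_trend", "moisture_trend"):
            if key in local_raw:
                local_raw[key] = tuple(local_raw[key])
        interactive = InteractiveConfig(**local_raw)

    return RunConfig(
        scenario=raw.get("scenario"),
        scenario_overrides=raw.get("scenario_overrides") or {},
        input_dir=raw.get("input_dir"),
        horizon_hours=float(raw.get("horizon_hours", 8.0)),
        output_dir=raw.get("output_dir", "."),
        params=params,
        montecarlo=montecarlo,
        interactive=interactive,
        reference_scar=raw.get("reference_scar"),
    )


def forward_date_inputs(landscape: Landscape, days_ahead: int,
                        fuel_trend: Tuple[float, ...] = DEFAULT_FUEL_TREND,
                        moisture_trend: Tuple[float, ...] =
                        DEFAULT_MOISTURE_TREND) -> Landscape:
    """Project fuel and moisture forward from the acquisition date.

    Each raster is multiplied by the trend factor ``1 + P(days_ahead)``
    with P the per-day polynomial (highest-degree coefficient first,
    constant last) and clamped to [0, 1]: e.g. a -0.01/day drying trend
    turns moisture 0.5 into 0.45 after 10 days.  The default linear
    trends (fuel +0.005/day curing, moisture -0.01/day drying) are
    documented stand-ins for history-fitted curves.  Projections beyond
    20 days are refused: the trends are not trusted further from the
    last acquisition.
    """
    if not (0 <= days_ahead <= MAX_FORWARD_DAYS):
        raise ValueError(
            f"days_ahead must lie in [0, {MAX_FORWARD_DAYS}], "
            f"got {days_ahead}"
        )
    out = landscape.copy()
    if days_ahead == 0:
        return out
    fuel_factor = 1.0 + float(np.polyval(fuel_trend, days_ahead))
    moisture_factor = 1.0 + float(np.polyval(moisture_trend, days_ahead))
    out.fuel = np.clip(out.fuel * fuel_factor, 0.0, 1.0)
    out.moisture = np.clip(out.moisture * moisture_factor, 0.0, 1.0)
    return out
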