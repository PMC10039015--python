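"""Synthetic landscape scenarios.

Generates fully valid input stacks (fuel, moisture, burn probability,
elevation, combustion rate, wind) with controlled structure: constant
fields, Gaussian-smoothed random fields with a chosen correlation
length, uniform slopes, firebreak stripes.  These emulate the spatial
character of the satellite-derived inputs only qualitatively; they carry
none of the radiometric artefacts of real imagery.

The named scenarios put the automaton in analytically interpretable
regimes: ``radial`` (uniform fuel, flat, calm — the configuration under
which the stochastic ignition threshold produces a radial front),
``wind_ellipse`` (strong uniform wind gating upwind spread below the
flammability threshold), ``slope`` (uniform incline favouring upslope
runs), ``firebreak`` (a zero-fuel stripe the fire cannot cross) and
``patchy`` (correlated fuel heterogeneity plus wind).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .landscape import GridGeometry, IgnitionSet, Landscape, validate_landscape

__all__ = ["FieldSpec", "ScenarioSpec", "gen_field", "gen_scenario",
           "SCENARIO_NAMES"]


@dataclass(frozen=True)
class FieldSpec:
    """Specification of one scalar input field.

    ``kind`` is "constant" (use ``value``) or "random": white noise
    smoothed by a Gaussian kernel of ``correlation_length`` cells, then
    linearly rescaled so its minimum and maximum hit ``lo`` and ``hi``.
    """

    kind: str = "constant"
    value: float = 0.0
    lo: float = 0.0
    hi: float = 1.0
    correlation_length: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "random"):
            raise ValueError(f"unknown field kind {self.kind!r}")
        if self.hi < self.lo:
            raise ValueError(f"hi ({self.hi}) < lo ({self.lo})")


def gen_field(spec: FieldSpec, geometry: GridGeometry,
              rng: np.random.Generator) -> np.ndarray:
    """Realise a field spec on a grid (deterministic for a given rng state)."""
    shape = geometry.shape
    if spec.kind == "constant":
        return np.full(shape, float(spec.value))
    noise = rng.standard_normal(shape)
    smooth = gaussian_filter(noise, sigma=spec.correlation_length)
    lo_s, hi_s = float(smooth.min()), float(smooth.max())
    if hi_s == lo_s:
        return np.full(shape, 0.5 * (spec.lo + spec.hi))
    return spec.lo + (smooth - lo_s) * (spec.hi - spec.lo) / (hi_s - lo_s)


@dataclass
class ScenarioSpec:
    """Parameters of a generated scenario."""

    name: str = "radial"
    n_rows: int = 101
    n_cols: int = 101
    cell_size: float = 20.0
    fuel: FieldSpec = field(default_factory=lambda: FieldSpec(value=1.0))
    moisture: FieldSpec = field(default_factory=lambda: FieldSpec(value=0.2))
    burn_prob: FieldSpec = field(default_factory=lambda: FieldSpec(value=1.0))
    combustion_rate: FieldSpec = field(
        default_factory=lambda: FieldSpec(value=0.9))
    elevation: str = "flat"          # flat | slope | ridge
    slope_deg: float = 30.0          # used by "slope" and "ridge"
    wind_speed: float = 0.0          # m/s, uniform
    wind_direction: float = 90.0     # degrees, direction blown toward
    firebreak_cols: Optional[Tuple[int, int]] = None  # [start, stop) columns
    ignition_cells: Optional[Tuple[Tuple[int, int], ...]] = None
    rng_seed: int = 0


def _elevation_field(spec: ScenarioSpec, geometry: GridGeometry) -> np.ndarray:
    rows = np.arange(geometry.n_rows, dtype=float)[:, None]
    cols = np.arange(geometry.n_cols, dtype=float)[None, :]
    if spec.elevation == "flat":
        return np.zeros(geometry.shape)
    rise = math.tan(math.radians(spec.slope_deg)) * geometry.cell_size
    if spec.elevation == "slope":
        # elevation increases northward: upslope = toward row 0
        return rise * (geometry.n_rows - 1 - rows) * np.ones_like(cols)
    if spec.elevation == "ridge":
        mid = (geometry.n_cols - 1) / 2.0
        return rise * (mid - np.abs(cols - mid)) * np.ones_like(rows)
    raise ValueError(f"unknown elevation model {spec.elevation!r}")


#: Built-in scenarios and the regime each exercises.
SCENARIO_NAMES = ("radial", "wind_ellipse", "slope", "firebreak", "patchy")


def _preset(name: str) -> ScenarioSpec:
    if name == "radial":
        return ScenarioSpec(name=name)
    if name == "firebreak":
        return ScenarioSpec(name=name, firebreak_cols=(75, 78))
    if name == "wind_ellipse":
        return ScenarioSpec(
            name=name,
            moisture=FieldSpec(value=0.5),
            burn_prob=FieldSpec(value=0.6),
            wind_speed=10.0,
            wind_direction=90.0,
        )
    if name == "slope":
        return ScenarioSpec(
            name=name,
            moisture=FieldSpec(value=0.5),
            burn_prob=FieldSpec(value=0.5),
            elevation="slope",
            slope_deg=30.0,
        )
    if name == "patchy":
        # wind-gated regime: with p(B|D) tied to fuel and moist fuels,
        # calm spread sits at the flammability threshold, so fire runs
        # need the downwind boost and the fuel-rich corridors
        return ScenarioSpec(
            name=name,
            n_rows=81,
            n_cols=81,
            fuel=FieldSpec(kind="random", lo=0.2, hi=1.0,
                           correlation_length=5.0),
            moisture=FieldSpec(kind="random", lo=0.45, hi=0.55,
                               correlation_length=5.0),
            burn_prob=FieldSpec(value=0.0),  # derived from fuel below
            wind_speed=10.0,
            wind_direction=90.0,
        )
    raise ValueError(
        f"unknown scenario {name!r}; choose one of {SCENARIO_NAMES}"
    )


def gen_scenario(name: str, **overrides) -> Tuple[Landscape, IgnitionSet]:
    """Generate a named scenario, optionally overriding spec fields.

    Returns a validated landscape and its ignition set (central cell
    unless ``ignition_cells`` overrides it).  Bit-reproducible for a
    fixed ``rng_seed``.
    """
    spec = _preset(name)
    for key, value in overrides.items():
        if not hasattr(spec, key):
            raise TypeError(f"unknown scenario override {key!r}")
        setattr(spec, key, value)

    geometry = GridGeometry(spec.n_rows, spec.n_cols, spec.cell_size)
    rng = np.random.default_rng(spec.rng_seed)
    fuel = gen_field(spec.fuel, geometry, rng)
    moisture = gen_field(spec.moisture, geometry, rng)
    burn_prob = gen_field(spec.burn_prob, geometry, rng)
    combustion = gen_field(spec.combustion_rate, geometry, rng)
    if name == "patchy":
        # burn probability tied to fuel: frequently burned == fuel rich
        burn_prob = 0.45 * fuel
    if spec.firebreak_cols is not None:
        lo, hi = spec.firebreak_cols
        fuel[:, lo:hi] = 0.0

    landscape = Landscape(
        geometry=geometry,
        fuel=fuel,
        moisture=moisture,
        burn_prob=burn_prob,
        elevation=_elevation_field(spec, geometry),
        combustion_rate=combustion,
        wind_speed=spec.wind_speed,
        wind_direction=spec.wind_direction,
    )
    landscape = validate_landscape(landscape)

    if spec.ignition_cells is not None:
        ignitions = IgnitionSet.at_cells(list(spec.ignition_cells))
    else:
        ignitions = IgnitionSet.at_cells(
            [(spec.n_rows // 2, spec.n_cols // 2)])
    ignitions.validate(geometry)
    return landscape, ignitions
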