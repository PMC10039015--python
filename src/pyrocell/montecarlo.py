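"""Monte Carlo ensemble mode: burn-probability surfaces.

Input variables that fluctuate faster than the observation cadence
(wind, fuel load, vegetation moisture, ignition placement) are randomly
perturbed between runs; aggregating the burned indicator over many runs
yields a per-cell burn-probability map highlighting the areas most
likely to burn.

Perturbations are truncated-normal offsets centred on the supplied
landscape values.  By default one offset per variable per run is drawn
and applied to the whole raster (the observation systems mis-estimate a
region-wide level, not individual pixels); per-cell noise is available
but off by default.  Ignition counts follow a Poisson law placed by an
optional spatial weight raster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.stats import truncnorm

from .engine import run_simulation
from .landscape import IgnitionSet, Landscape
from .params import ModelParams

__all__ = [
    "VariablePerturbation",
    "PerturbationSpec",
    "BurnProbabilityMap",
    "perturb_inputs",
    "draw_ignitions",
    "run_monte_carlo",
]


@dataclass(frozen=True)
class VariablePerturbation:
    """Truncated-normal perturbation of one input variable.

    ``sd`` is the standard deviation of the additive offset;
    ``bounds`` are the legal limits the perturbed values must respect
    (None to leave a side open, e.g. wind direction wraps instead).
    """

    sd: float = 0.0
    bounds: Tuple[Optional[float], Optional[float]] = (None, None)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        lo, hi = self.bounds
        if lo is not None and hi is not None and hi < lo:
            raise ValueError(f"invalid bounds {self.bounds}")


@dataclass
class PerturbationSpec:
    """What to vary between ensemble runs."""

    wind_speed: VariablePerturbation = field(
        default_factory=lambda: VariablePerturbation(sd=0.0, bounds=(0.0, None)))
    wind_direction: VariablePerturbation = field(
        default_factory=VariablePerturbation)
    fuel: VariablePerturbation = field(
        default_factory=lambda: VariablePerturbation(sd=0.0, bounds=(0.0, 1.0)))
    moisture: VariablePerturbation = field(
        default_factory=lambda: VariablePerturbation(sd=0.0, bounds=(0.0, 1.0)))
    #: expected ignition count (Poisson); None keeps the supplied ignitions
    ignition_rate: Optional[float] = None
    #: optional spatial weight raster for ignition placement
    ignition_weight: Optional[np.ndarray] = None
    #: draw an independent offset per cell instead of one per run
    per_cell: bool = False


@dataclass
class BurnProbabilityMap:
    """Per-cell fraction of ensemble runs in which the cell burned."""

    probability: np.ndarray
    n_runs: int
    rng_seed: int

    def __post_init__(self) -> None:
        p = self.probability
        if p.size and (p.min() < 0.0 or p.max() > 1.0):
            raise ValueError("probabilities must lie in [0, 1]")


def _offset(value: np.ndarray, pert: VariablePerturbation,
            rng: np.random.Generator, per_cell: bool,
            wrap_360: bool = False) -> np.ndarray:
    """Truncated-normal offset keeping every value inside the bounds."""
    value = np.asarray(value, dtype=float)
    if pert.sd == 0.0:
        return value
    lo, hi = pert.bounds
    if wrap_360:
        delta = rng.normal(0.0, pert.sd,
                           size=value.shape if per_cell else None)
        return np.mod(value + delta, 360.0)
    if per_cell:
        a = -np.inf if lo is None else (lo - value) / pert.sd
        b = np.inf if hi is None else (hi - value) / pert.sd
        delta = truncnorm.rvs(a, b, scale=pert.sd, size=value.shape,
                              random_state=rng)
        return value + delta
    # one offset for the whole raster, truncated so no cell leaves bounds
    a = -np.inf if lo is None else (lo - float(value.min())) / pert.sd
    b = np.inf if hi is None else (hi - float(value.max())) / pert.sd
    if a >= b:  # raster already spans the full legal range
        return value
    delta = float(truncnorm.rvs(a, b, scale=pert.sd, random_state=rng))
    return value + delta


def draw_ignitions(spec: PerturbationSpec, landscape: Landscape,
                   rng: np.random.Generator) -> IgnitionSet:
    """Poisson number of ignition cells placed by the spatial weight."""
    n_rows, n_cols = landscape.geometry.shape
    count = int(rng.poisson(spec.ignition_rate))
    if count == 0:
        return IgnitionSet([])
    if spec.ignition_weight is not None:
        w = np.asarray(spec.ignition_weight, dtype=float).ravel()
        if w.shape[0] != n_rows * n_cols:
            raise ValueError("ignition_weight does not match the grid")
        if w.min() < 0 or w.sum() <= 0:
            raise ValueError("ignition_weight must be non-negative, not all 0")
        p = w / w.sum()
    else:
        p = None
    flat = rng.choice(n_rows * n_cols, size=count, replace=True, p=p)
    cells = [(int(i // n_cols), int(i % n_cols)) for i in flat]
    return IgnitionSet.at_cells(cells)


def perturb_inputs(landscape: Landscape, spec: PerturbationSpec,
                   rng: np.random.Generator
                   ) -> Tuple[Landscape, Optional[IgnitionSet]]:
    """Perturbed copy of the landscape plus drawn ignitions (or None when
    the spec keeps the caller's ignition set)."""
    out = landscape.copy()
    per_cell = spec.per_cell
    out.fuel = np.clip(_offset(out.fuel, spec.fuel, rng, per_cell), 0.0, 1.0)
    out.moisture = np.clip(
        _offset(out.moisture, spec.moisture, rng, per_cell), 0.0, 1.0)

    ws = np.asarray(out.wind_speed, dtype=float)
    ws_new = _offset(ws, spec.wind_speed, rng, per_cell and ws.ndim == 2)
    out.wind_speed = float(ws_new) if ws_new.ndim == 0 else ws_new
    wd = np.asarray(out.wind_direction, dtype=float)
    wd_new = _offset(wd, spec.wind_direction, rng,
                     per_cell and wd.ndim == 2, wrap_360=True)
    out.wind_direction = float(wd_new) if wd_new.ndim == 0 else wd_new

    ignitions = None
    if spec.ignition_rate is not None:
        ignitions = draw_ignitions(spec, landscape, rng)
    return out, ignitions


def run_monte_carlo(
    landscape: Landscape,
    spec: PerturbationSpec,
    n_runs: int,
    horizon_hours: float,
    params: Optional[ModelParams] = None,
    ignitions: Optional[IgnitionSet] = None,
    n_steps: Optional[int] = None,
) -> BurnProbabilityMap:
    """Aggregate ``n_runs`` perturbed simulations into a probability map.

    The master seed (``params.rng_seed``) deterministically spawns one
    child seed per run, so ensembles are reproducible and runs are
    mutually independent.
    """
    import warnings

    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    params = params or ModelParams()
    master = np.random.SeedSequence(params.rng_seed)
    children = master.spawn(n_runs)
    counts = np.zeros(landscape.geometry.shape, dtype=np.int64)

    for child in children:
        rng = np.random.default_rng(child)
        perturbed, drawn = perturb_inputs(landscape, spec, rng)
        run_ign = drawn if drawn is not None else ignitions
        if run_ign is None:
            raise ValueError(
                "no ignitions: supply an IgnitionSet or set spec.ignition_rate"
            )
        run_seed = int(rng.integers(0, 2**31 - 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty Poisson draws are fine
            outcome = run_simulation(
                perturbed, run_ign, horizon_hours,
                params.with_(rng_seed=run_seed),
                n_steps=n_steps, record_events=False,
            )
        counts += outcome.ever_burned

    return BurnProbabilityMap(
        probability=counts / float(n_runs),
        n_runs=n_runs,
        rng_seed=params.rng_seed,
    )
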