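"""The fire-spread cellular automaton.

Each time step, every unburned cell is screened by a five-test cascade:
(1) at least one Moore neighbour on fire, (2) fuel present, (3) combined
flammability fF = p(B|D) * fe * fW * fM from the elevation, wind and
moisture effects, (4) fF above the minimum threshold v1, and (5) a
uniform draw below the ignition threshold.  Burning cells consume fuel
geometrically, may extinguish by fuel exhaustion or by the extinction
probability pE = V * exp(-(b1*M)**b2) crossing v2, and cell moisture
follows a diurnal quartic multiplier modulated by nearby fire.

All cells update synchronously: ignition and extinction decisions in a
step are evaluated against the fire map at the start of the step.  The
grid update is vectorised; :func:`ignition_test` and friends provide the
equivalent per-cell path used for unit checks and calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .landscape import (
    IgnitionSet,
    Landscape,
    MOORE_OFFSETS,
    NeighborContext,
    bearing_toward_center,
    neighbor_context,
    validate_landscape,
)
from .params import ModelParams

__all__ = [
    "UNBURNED",
    "BURNING",
    "BURNED_OUT",
    "FlammabilityResult",
    "FireState",
    "FireOutcome",
    "elevation_effect",
    "wind_effect",
    "moisture_effect",
    "combined_flammability",
    "moisture_flammability_factor",
    "fuel_update",
    "hourly_moisture",
    "timestep_for_resolution",
    "ignition_test",
    "extinction_test",
    "flammability_grids",
    "step",
    "run_simulation",
]

# cell status codes (also the burn-scar encoding: 1 burned, 2 burning)
UNBURNED = 0
BURNING = 2
BURNED_OUT = 1

SECONDS_PER_DAY = 86400.0


# ---------------------------------------------------------------------------
# point-wise model equations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlammabilityResult:
    """Factor decomposition of a cell's combined flammability."""

    fe: float
    fw: float
    fm: float
    ff: float
    n_burning_neighbors: int


def elevation_effect(ctx: NeighborContext, alpha: float) -> float:
    """Elevation effect fe: sum of exp(alpha * slope * sign) over burning
    neighbours; sign is +1 when the burning neighbour is below the cell
    (fire climbs), -1 when above."""
    total = 0.0
    for nb in ctx.neighbors:
        if nb.on_fire:
            total += math.exp(alpha * nb.slope_deg * nb.elev_sign)
    return total


def wind_effect(
    ctx: NeighborContext,
    wind_speed: float,
    wind_direction: float,
    cw1: float,
    cw2: float,
    cw3: float,
) -> float:
    """Wind effect fW summed over burning neighbours.

    For each burning neighbour the angle D is measured between the wind
    vector (direction the wind blows toward) and the bearing from that
    neighbour toward the central cell; wind aligned with the spread
    direction leaves the exponential damping at 1, opposing wind damps
    the term via cos(D) - 1 <= 0.  A calm neighbour term contributes cw1
    so that spread remains possible in still air.
    """
    total = 0.0
    for nb in ctx.neighbors:
        if not nb.on_fire:
            continue
        if wind_speed <= 0.0:
            total += cw1
            continue
        d = math.radians(wind_direction - nb.bearing_deg)
        total += (
            cw1
            * math.exp(cw2 * wind_speed * (math.cos(d) - 1.0))
            * wind_speed ** cw3
        )
    return total


def moisture_effect(moisture: float, b1: float) -> float:
    """Moisture effect fM = exp(-b1 * M)."""
    return math.exp(-b1 * moisture)


def combined_flammability(burn_prob: float, fe: float, fw: float, fm: float
                          ) -> float:
    """Combined flammability fF = p(B|D) * fe * fW * fM."""
    return burn_prob * fe * fw * fm


def moisture_flammability_factor(moisture: float, b1: float, b2: int) -> float:
    """Fuel-consumption moisture factor I = exp(-(b1*M)**b2).

    With b2 a positive even integer this equals the nominal
    1 / exp((-b1*M)**b2) form and decreases monotonically with moisture,
    staying in (0, 1] with I = 1 at M = 0.
    """
    return math.exp(-((b1 * moisture) ** b2))


def fuel_update(fuel_prev: float, consumption_rate: float, i_factor: float
                ) -> float:
    """One step of fuel consumption: B_t = B_{t-1} * (1 - C*I)."""
    return fuel_prev - fuel_prev * consumption_rate * i_factor


def extinction_probability(moisture: float, consumption_rate: float,
                           b1: float, b2: int) -> float:
    """Extinction probability pE = V * exp(-(b1*M)**b2)."""
    return consumption_rate * moisture_flammability_factor(moisture, b1, b2)


def hourly_moisture(
    moisture_daily: float,
    t_seconds: float,
    n_burning_neighbors: int,
    consumption_rate: float,
    coeffs: Tuple[float, float, float, float, float],
) -> float:
    """Moisture at hour t from the daily moisture M.

    ``M_t = clamp(P(t) * M * (1 - C*N/100), 0, 1)`` where P is the
    diurnal quartic (coefficients c4..c0, argument seconds since local
    midnight), N the number of burning neighbours and C the fuel
    consumption rate: nearby fire dries the cell.
    """
    if not (0.0 <= t_seconds <= SECONDS_PER_DAY):
        raise ValueError(f"t must lie in [0, {SECONDS_PER_DAY:.0f}] s, "
                         f"got {t_seconds}")
    c4, c3, c2, c1, c0 = coeffs
    p = (((c4 * t_seconds + c3) * t_seconds + c2) * t_seconds + c1) \
        * t_seconds + c0
    mt = p * moisture_daily * (1.0 - consumption_rate * n_burning_neighbors
                               / 100.0)
    return min(max(mt, 0.0), 1.0)


def timestep_for_resolution(cell_size: float, params: ModelParams) -> float:
    """CA time step in seconds for a given cell size.

    Linear in cell size (a front crossing one cell per step moves at a
    fixed calibrated speed): 20 m -> 38.61 s, 500 m -> 965.25 s.
    """
    if cell_size <= 0:
        raise ValueError(f"cell_size must be > 0, got {cell_size}")
    return params.timestep_20m * cell_size / 20.0


# ---------------------------------------------------------------------------
# per-cell ignition / extinction decisions
# ---------------------------------------------------------------------------

def ignition_test(
    state: "FireState",
    row: int,
    col: int,
    landscape: Landscape,
    params: ModelParams,
    rng: np.random.Generator,
) -> Tuple[bool, Optional[FlammabilityResult]]:
    """Five-test ignition cascade for one unburned cell.

    Tests short-circuit in order: (1) a burning Moore neighbour exists;
    (2) the cell holds fuel; (3) combined flammability is computed;
    (4) it exceeds v1; (5) a uniform draw falls below the ignition
    threshold.  The random generator is consumed only when test 5 is
    reached.  Returns (ignites, flammability-or-None); the result is
    None whenever tests 1-2 already failed.
    """
    fire = state.status == BURNING
    ctx = neighbor_context(landscape, fire, row, col)
    if ctx.n_on_fire == 0:
        return False, None
    if state.fuel[row, col] <= 0.0 or landscape.nodata[row, col]:
        return False, None
    fe = elevation_effect(ctx, params.alpha)
    fw = wind_effect(
        ctx,
        landscape.wind_speed_at(row, col),
        landscape.wind_direction_at(row, col),
        params.cw1,
        params.cw2,
        params.cw3,
    )
    fm = moisture_effect(float(state.moisture[row, col]), params.b1)
    ff = combined_flammability(float(landscape.burn_prob[row, col]), fe, fw, fm)
    result = FlammabilityResult(fe=fe, fw=fw, fm=fm, ff=ff,
                                n_burning_neighbors=ctx.n_on_fire)
    if ff <= params.v1:
        return False, result
    ignites = bool(rng.random() < params.ignite_threshold)
    return ignites, result


def extinction_test(
    fuel: float,
    moisture: float,
    consumption_rate: float,
    params: ModelParams,
) -> Tuple[bool, float]:
    """Extinction decision for one burning cell.

    A cell with no fuel left (below the fuel floor) always goes out.
    Otherwise pE = V * exp(-(b1*M)**b2) is computed and, under the
    default rule, the fire goes out when pE exceeds v2; under the
    alternative "moisture" rule it goes out when M < v2.  Returns
    (extinguishes, pE).
    """
    if fuel <= params.fuel_floor:
        return True, 0.0
    pe = extinction_probability(moisture, consumption_rate, params.b1,
                                params.b2)
    if params.extinction_rule == "moisture":
        return moisture < params.v2, pe
    return pe > params.v2, pe


# ---------------------------------------------------------------------------
# grid state and vectorised stepping
# ---------------------------------------------------------------------------

@dataclass
class FireState:
    """Dynamic per-cell state of a run at one time step."""

    status: np.ndarray        # uint8: UNBURNED / BURNING / BURNED_OUT
    fuel: np.ndarray          # fraction, non-increasing
    moisture: np.ndarray      # current hourly moisture M_t
    ignition_step: np.ndarray   # int, -1 where never ignited
    extinction_step: np.ndarray  # int, -1 where never extinguished
    step_index: int = 0
    clock_s: float = 0.0      # seconds since local midnight

    @classmethod
    def initial(cls, landscape: Landscape, params: ModelParams) -> "FireState":
        shape = landscape.geometry.shape
        state = cls(
            status=np.full(shape, UNBURNED, dtype=np.uint8),
            fuel=landscape.fuel.astype(float).copy(),
            moisture=landscape.moisture.astype(float).copy(),
            ignition_step=np.full(shape, -1, dtype=np.int32),
            extinction_step=np.full(shape, -1, dtype=np.int32),
            step_index=0,
            clock_s=params.start_time_s,
        )
        return state

    def copy(self) -> "FireState":
        return FireState(
            status=self.status.copy(),
            fuel=self.fuel.copy(),
            moisture=self.moisture.copy(),
            ignition_step=self.ignition_step.copy(),
            extinction_step=self.extinction_step.copy(),
            step_index=self.step_index,
            clock_s=self.clock_s,
        )

    def ignite_cells(self, cells, step: Optional[int] = None) -> None:
        """Force-ignite cells (hot pixels are observations of fire, so
        they skip the flammability cascade); a cell can only start
        burning while it still holds fuel."""
        s = self.step_index if step is None else step
        for row, col in cells:
            if self.status[row, col] == UNBURNED and self.fuel[row, col] > 0:
                self.status[row, col] = BURNING
                self.ignition_step[row, col] = s


def _shifted(arr: np.ndarray, dr: int, dc: int, fill) -> np.ndarray:
    """out[r, c] = arr[r+dr, c+dc], boundary filled."""
    n, m = arr.shape
    out = np.full_like(arr, fill)
    dest_r = slice(max(0, -dr), n - max(0, dr))
    dest_c = slice(max(0, -dc), m - max(0, dc))
    src_r = slice(max(0, dr), n - max(0, -dr))
    src_c = slice(max(0, dc), m - max(0, -dc))
    out[dest_r, dest_c] = arr[src_r, src_c]
    return out


class _Stencil:
    """Pre-computed per-offset elevation and wind term grids.

    Both depend only on static landscape fields, so they are computed
    once per (landscape, params) pair and reused every step.
    """

    def __init__(self, landscape: Landscape, params: ModelParams) -> None:
        geom = landscape.geometry
        elev = landscape.elevation.astype(float)
        speed = landscape.wind_speed_grid()
        direction = landscape.wind_direction_grid()
        self.elev_terms: List[np.ndarray] = []
        self.wind_terms: List[np.ndarray] = []
        for dr, dc in MOORE_OFFSETS:
            dz = _shifted(elev, dr, dc, 0.0) - elev  # neighbour minus centre
            # boundary rows/cols never matter (fire fill is False there)
            dist = geom.cell_size * math.hypot(dr, dc)
            slope = np.degrees(np.arctan(np.abs(dz) / dist))
            sign = np.where(dz > 0, -1.0, 1.0)
            self.elev_terms.append(np.exp(params.alpha * slope * sign))

            bearing = bearing_toward_center(dr, dc)
            d = np.radians(direction - bearing)
            with np.errstate(invalid="ignore"):
                windy = (
                    params.cw1
                    * np.exp(params.cw2 * speed * (np.cos(d) - 1.0))
                    * np.power(np.maximum(speed, 0.0), params.cw3)
                )
            self.wind_terms.append(np.where(speed > 0.0, windy, params.cw1))


def flammability_grids(
    landscape: Landscape,
    fire: np.ndarray,
    moisture: np.ndarray,
    params: ModelParams,
    stencil: Optional[_Stencil] = None,
) -> Dict[str, np.ndarray]:
    """Grid-wide fe, fW, fM, fF and burning-neighbour count N for a given
    fire mask and current moisture field."""
    if stencil is None:
        stencil = _Stencil(landscape, params)
    shape = landscape.geometry.shape
    fe = np.zeros(shape)
    fw = np.zeros(shape)
    n_burning = np.zeros(shape, dtype=np.int32)
    for k, (dr, dc) in enumerate(MOORE_OFFSETS):
        f_k = _shifted(fire, dr, dc, False)
        fe += stencil.elev_terms[k] * f_k
        fw += stencil.wind_terms[k] * f_k
        n_burning += f_k
    fm = np.exp(-params.b1 * moisture)
    ff = landscape.burn_prob * fe * fw * fm
    return {"fe": fe, "fw": fw, "fm": fm, "ff": ff, "n_burning": n_burning}


@dataclass
class StepEvents:
    """Cells that changed in one step, with their decision quantities."""

    step: int
    ignited: List[Tuple[int, int, float]] = field(default_factory=list)
    extinguished: List[Tuple[int, int, float]] = field(default_factory=list)
    consumed: List[Tuple[int, int, float]] = field(default_factory=list)


def step(
    state: FireState,
    landscape: Landscape,
    params: ModelParams,
    rng: np.random.Generator,
    stencil: Optional[_Stencil] = None,
    record_events: bool = True,
) -> Tuple[FireState, StepEvents]:
    """Advance the automaton one synchronous step.

    All decisions use the fire map at the start of the step.  Order of
    module evaluation: hourly moisture (clock + neighbours on fire),
    flammability/ignition on unburned cells, extinction and fuel
    consumption on burning cells.  One full-grid uniform draw is
    consumed per step (row-major), so runs are bit-reproducible for a
    given seed regardless of which cells are candidates.
    """
    if stencil is None:
        stencil = _Stencil(landscape, params)
    new = state.copy()
    fire = state.status == BURNING
    events = StepEvents(step=state.step_index)

    grids = flammability_grids(landscape, fire, state.moisture, params,
                               stencil)
    n_burning = grids["n_burning"]

    # hourly moisture from the daily raster, modulated by nearby fire
    c4, c3, c2, c1, c0 = params.moisture_poly
    t = state.clock_s % SECONDS_PER_DAY
    p_t = (((c4 * t + c3) * t + c2) * t + c1) * t + c0
    m_t = np.clip(
        p_t * landscape.moisture
        * (1.0 - landscape.combustion_rate * n_burning / 100.0),
        0.0, 1.0,
    )
    new.moisture = m_t

    # ignition: five tests, evaluated against the pre-step fire map
    u = rng.random(state.status.shape)
    candidates = (
        (state.status == UNBURNED)
        & (state.fuel > 0.0)
        & ~landscape.nodata
        & (n_burning > 0)
    )
    ignite = candidates & (grids["ff"] > params.v1) \
        & (u < params.ignite_threshold)
    new.status[ignite] = BURNING
    new.ignition_step[ignite] = state.step_index

    # extinction and fuel consumption on cells burning at step start
    i_factor = np.exp(-((params.b1 * state.moisture) ** params.b2))
    pe = landscape.combustion_rate * i_factor
    out_of_fuel = state.fuel <= params.fuel_floor
    if params.extinction_rule == "moisture":
        rule_out = state.moisture < params.v2
    else:
        rule_out = pe > params.v2
    extinguish = fire & (out_of_fuel | rule_out)
    new.status[extinguish] = BURNED_OUT
    new.extinction_step[extinguish] = state.step_index

    consumed = np.where(fire, state.fuel * landscape.combustion_rate
                        * i_factor, 0.0)
    new.fuel = state.fuel - consumed

    if record_events:
        for row, col in np.argwhere(ignite):
            events.ignited.append((int(row), int(col),
                                   float(grids["ff"][row, col])))
        for row, col in np.argwhere(extinguish):
            events.extinguished.append((int(row), int(col),
                                        float(pe[row, col])))
        for row, col in np.argwhere(fire):
            events.consumed.append((int(row), int(col),
                                    float(consumed[row, col])))

    new.step_index = state.step_index + 1
    new.clock_s = state.clock_s + timestep_for_resolution(
        landscape.geometry.cell_size, params)
    return new, events


# ---------------------------------------------------------------------------
# whole-run driver
# ---------------------------------------------------------------------------

@dataclass
class FireOutcome:
    """Result of one simulation run.

    ``scar`` uses the status encoding 0 unburned / 1 burned out /
    2 still burning at the horizon; ``ever_burned`` covers both burned
    states.
    """

    scar: np.ndarray
    ignition_step: np.ndarray
    extinction_step: np.ndarray
    fuel_remaining: np.ndarray
    initial_fuel: np.ndarray
    events: pd.DataFrame
    front_sizes: np.ndarray
    seed_cells: List[Tuple[int, int]]
    n_steps: int
    dt_seconds: float
    params: ModelParams
    landscape: Landscape

    @property
    def ever_burned(self) -> np.ndarray:
        return self.scar != UNBURNED


def _events_frame(all_events: List[StepEvents]) -> pd.DataFrame:
    rows = []
    for ev in all_events:
        for r, c, ff in ev.ignited:
            rows.append((ev.step, r, c, "ignite", ff, np.nan))
        for r, c, pe in ev.extinguished:
            rows.append((ev.step, r, c, "extinguish", np.nan, pe))
        for r, c, d in ev.consumed:
            rows.append((ev.step, r, c, "consume", d, np.nan))
    return pd.DataFrame(rows, columns=["step", "row", "col", "event",
                                       "value", "pe"])


def run_simulation(
    landscape: Landscape,
    ignitions: IgnitionSet,
    horizon_hours: float,
    params: Optional[ModelParams] = None,
    n_steps: Optional[int] = None,
    record_events: bool = True,
) -> FireOutcome:
    """Run the automaton from an ignition set for a forecast horizon.

    The number of steps is ``ceil(horizon_hours * 3600 / dt)`` with dt
    the resolution-dependent time step, unless ``n_steps`` overrides it.
    Hot-pixel ignitions fire unconditionally when the elapsed time
    reaches their timestamp.  Fully reproducible for a given
    ``params.rng_seed``.
    """
    import warnings

    params = params or ModelParams()
    landscape = validate_landscape(landscape)
    ignitions.validate(landscape.geometry)
    if horizon_hours <= 0:
        raise ValueError("horizon must be positive")
    dt = timestep_for_resolution(landscape.geometry.cell_size, params)
    if n_steps is None:
        n_steps = int(math.ceil(horizon_hours * 3600.0 / dt))
    if len(ignitions) == 0:
        warnings.warn("empty ignition set: the scar will be empty",
                      stacklevel=2)

    rng = np.random.default_rng(params.rng_seed)
    stencil = _Stencil(landscape, params)
    state = FireState.initial(landscape, params)
    initial_fuel = state.fuel.copy()

    pending = sorted(ignitions, key=lambda e: e[2])
    seed_cells = [(r, c) for r, c, _ in pending]
    all_events: List[StepEvents] = []
    front_sizes = np.zeros(n_steps, dtype=np.int64)

    for k in range(n_steps):
        elapsed = k * dt
        due = [e for e in pending if e[2] <= elapsed]
        if due:
            state.ignite_cells([(r, c) for r, c, _ in due])
            pending = [e for e in pending if e[2] > elapsed]
        state, events = step(state, landscape, params, rng, stencil,
                             record_events=record_events)
        front_sizes[k] = int(np.count_nonzero(state.status == BURNING))
        if record_events:
            all_events.append(events)
        if front_sizes[k] == 0 and not pending:
            front_sizes = front_sizes[: k + 1]
            break

    return FireOutcome(
        scar=state.status.copy(),
        ignition_step=state.ignition_step.copy(),
        extinction_step=state.extinction_step.copy(),
        fuel_remaining=state.fuel.copy(),
        initial_fuel=initial_fuel,
        events=_events_frame(all_events),
        front_sizes=front_sizes,
        seed_cells=seed_cells,
        n_steps=int(front_sizes.size),
        dt_seconds=dt,
        params=params,
        landscape=landscape,
    )
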