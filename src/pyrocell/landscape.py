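"""Raster data model: grid geometry, landscape stack, neighbourhoods.

A :class:`Landscape` is a stack of co-registered single-band rasters
(fuel, moisture, burn probability, elevation, combustion rate) plus wind
fields (raster or scalar) sharing one :class:`GridGeometry`.  Rows are
stored row-major with row 0 at the northern edge, matching the usual
north-up GeoTIFF layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "GridGeometry",
    "Landscape",
    "Neighbor",
    "NeighborContext",
    "IgnitionSet",
    "MOORE_OFFSETS",
    "validate_landscape",
    "neighbor_context",
    "bearing_toward_center",
]

#: The 8 Moore-neighbourhood offsets in row-major order.
MOORE_OFFSETS: Tuple[Tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


@dataclass(frozen=True)
class GridGeometry:
    """Regular raster grid: shape, cell size and map-coordinate anchor.

    ``origin`` is the map coordinate of the outer corner of cell (0, 0);
    with ``row0_is_north`` (the default) that is the north-west corner and
    y decreases with increasing row index.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin: Tuple[float, float] = (0.0, 0.0)
    row0_is_north: bool = True

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def contains(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols

    def cell_center(self, row: int, col: int) -> Tuple[float, float]:
        """Map coordinate (x, y) of a cell center."""
        x0, y0 = self.origin
        x = x0 + (col + 0.5) * self.cell_size
        sgn = -1.0 if self.row0_is_north else 1.0
        y = y0 + sgn * (row + 0.5) * self.cell_size
        return (x, y)

    def index_of(self, x: float, y: float) -> Tuple[int, int]:
        """Row/col of the cell containing a map coordinate."""
        x0, y0 = self.origin
        col = int(math.floor((x - x0) / self.cell_size))
        sgn = -1.0 if self.row0_is_north else 1.0
        row = int(math.floor(sgn * (y - y0) / self.cell_size))
        return (row, col)


WindField = Union[float, np.ndarray]

_RANGE_01 = ("fuel", "moisture", "burn_prob", "combustion_rate")


@dataclass
class Landscape:
    """Co-registered input rasters driving the fire simulation.

    Fractional rasters (fuel, moisture, burn probability, combustion
    rate) live in [0, 1]; elevation is in metres.  Wind may be a scalar
    or a per-cell raster; ``wind_direction`` is the direction the wind
    blows *toward*, in degrees clockwise from grid north.  ``nodata``
    cells are unburnable barriers.
    """

    geometry: GridGeometry
    fuel: np.ndarray
    moisture: np.ndarray
    burn_prob: np.ndarray
    elevation: np.ndarray
    combustion_rate: np.ndarray
    wind_speed: WindField = 0.0
    wind_direction: WindField = 0.0
    nodata: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.nodata is None:
            self.nodata = np.zeros(self.geometry.shape, dtype=bool)

    # -- convenience accessors -------------------------------------------
    def wind_speed_at(self, row: int, col: int) -> float:
        if np.isscalar(self.wind_speed):
            return float(self.wind_speed)
        return float(self.wind_speed[row, col])

    def wind_direction_at(self, row: int, col: int) -> float:
        if np.isscalar(self.wind_direction):
            return float(self.wind_direction)
        return float(self.wind_direction[row, col])

    def wind_speed_grid(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.wind_speed, dtype=float),
                               self.geometry.shape)

    def wind_direction_grid(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.wind_direction, dtype=float),
                               self.geometry.shape)

    def copy(self) -> "Landscape":
        def _cp(a):
            return a.copy() if isinstance(a, np.ndarray) else a

        return Landscape(
            geometry=self.geometry,
            fuel=self.fuel.copy(),
            moisture=self.moisture.copy(),
            burn_prob=self.burn_prob.copy(),
            elevation=self.elevation.copy(),
            combustion_rate=self.combustion_rate.copy(),
            wind_speed=_cp(self.wind_speed),
            wind_direction=_cp(self.wind_direction),
            nodata=self.nodata.copy(),
        )


@dataclass(frozen=True)
class Neighbor:
    """One Moore neighbour of a central cell.

    ``slope_deg`` is the (non-negative) slope angle between the two cell
    centers; ``elev_sign`` is +1 when the neighbour lies below the
    central cell (or at equal elevation) and -1 when above;
    ``bearing_deg`` is the bearing from the neighbour toward the central
    cell, degrees clockwise from grid north.
    """

    row: int
    col: int
    on_fire: bool
    slope_deg: float
    elev_sign: int
    bearing_deg: float


@dataclass(frozen=True)
class NeighborContext:
    """Moore-8 context of a central cell; boundary cells have fewer."""

    row: int
    col: int
    neighbors: Tuple[Neighbor, ...]

    @property
    def n_on_fire(self) -> int:
        return sum(1 for nb in self.neighbors if nb.on_fire)


@dataclass
class IgnitionSet:
    """Set of ignition cells (hot pixels): (row, col, time-in-seconds).

    Hot pixels are observations of active fire, so they ignite
    unconditionally once the simulation clock reaches their time (time 0
    = start of the run).  Duplicate cells collapse to their earliest
    time.
    """

    entries: List[Tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        best: dict = {}
        for row, col, t in self.entries:
            key = (int(row), int(col))
            t = float(t)
            if key not in best or t < best[key]:
                best[key] = t
        self.entries = [(r, c, t) for (r, c), t in sorted(best.items())]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def validate(self, geometry: GridGeometry) -> "IgnitionSet":
        for row, col, _ in self.entries:
            if not geometry.contains(row, col):
                raise ValueError(f"ignition cell ({row}, {col}) is off-grid")
        return self

    @classmethod
    def at_cells(cls, cells: Sequence[Tuple[int, int]], time: float = 0.0
                 ) -> "IgnitionSet":
        return cls([(r, c, time) for r, c in cells])


def validate_landscape(landscape: Landscape) -> Landscape:
    """Check geometry conformance and value ranges of all rasters.

    Raises ``ValueError`` naming every offending raster; returns the
    landscape (with nodata cells forced to zero fuel) when valid.
    """
    shape = landscape.geometry.shape
    geom_bad: List[str] = []
    range_bad: List[str] = []

    rasters = {
        "fuel": landscape.fuel,
        "moisture": landscape.moisture,
        "burn_prob": landscape.burn_prob,
        "elevation": landscape.elevation,
        "combustion_rate": landscape.combustion_rate,
        "nodata": landscape.nodata,
    }
    for name in ("wind_speed", "wind_direction"):
        value = getattr(landscape, name)
        if not np.isscalar(value):
            rasters[name] = np.asarray(value)

    for name, arr in rasters.items():
        if np.asarray(arr).shape != shape:
            geom_bad.append(f"{name} has shape {np.asarray(arr).shape}, "
                            f"expected {shape}")
    if geom_bad:
        raise ValueError("geometry mismatch: " + "; ".join(geom_bad))

    for name in _RANGE_01:
        arr = rasters[name]
        valid = ~landscape.nodata
        vals = np.asarray(arr)[valid]
        if vals.size and (np.nanmin(vals) < 0.0 or np.nanmax(vals) > 1.0):
            range_bad.append(name)
    ws = landscape.wind_speed
    if np.isscalar(ws):
        if ws < 0:
            range_bad.append("wind_speed")
    elif np.any(np.asarray(ws) < 0):
        range_bad.append("wind_speed")
    if range_bad:
        raise ValueError(
            "values out of range in raster(s): " + ", ".join(range_bad)
        )

    # nodata cells are unburnable barriers
    landscape.fuel = np.where(landscape.nodata, 0.0, landscape.fuel)
    return landscape


def bearing_toward_center(dr: int, dc: int) -> float:
    """Bearing (deg clockwise from grid north) from the neighbour at
    offset ``(dr, dc)`` toward the central cell, on a north-up grid."""
    # neighbour -> center vector in map axes: east = -dc, north = +dr
    return math.degrees(math.atan2(-dc, dr)) % 360.0


def neighbor_context(
    landscape: Landscape,
    fire_state: np.ndarray,
    row: int,
    col: int,
) -> NeighborContext:
    """Moore-8 neighbourhood of ``(row, col)`` with slope geometry.

    ``fire_state`` is a boolean raster marking burning cells.  The slope
    angle uses the horizontal center-to-center distance (cell size, or
    cell size * sqrt(2) for diagonal neighbours).  Flat ties get
    ``elev_sign = +1`` with zero slope, so they contribute neutrally to
    the elevation effect.
    """
    geom = landscape.geometry
    if not geom.contains(row, col):
        raise IndexError(f"cell ({row}, {col}) is off-grid")

    z0 = float(landscape.elevation[row, col])
    neighbors = []
    for dr, dc in MOORE_OFFSETS:
        r, c = row + dr, col + dc
        if not geom.contains(r, c):
            continue
        dz = float(landscape.elevation[r, c]) - z0
        dist = geom.cell_size * math.hypot(dr, dc)
        slope = math.degrees(math.atan(abs(dz) / dist))
        sign = -1 if dz > 0 else 1
        neighbors.append(
            Neighbor(
                row=r,
                col=c,
                on_fire=bool(fire_state[r, c]),
                slope_deg=slope,
                elev_sign=sign,
                bearing_deg=bearing_toward_center(dr, dc),
            )
        )
    return NeighborContext(row=row, col=col, neighbors=tuple(neighbors))
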