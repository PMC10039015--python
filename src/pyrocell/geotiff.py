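"""GeoTIFF raster and hot-pixel CSV input/output.

Single-band float32 GeoTIFFs carry the grid geometry in the standard
tags (ModelPixelScale, ModelTiepoint) plus the GDAL nodata convention;
reading honours the same tags and falls back to a unit grid at the
origin when they are absent.  Hot pixels load from CSV with either
``row``/``col`` or map-coordinate ``x``/``y`` (or ``lon``/``lat``)
columns and an optional ISO-8601 ``timestamp``.
"""

from __future__ import annotations

import os
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import tifffile

from .landscape import GridGeometry, IgnitionSet, Landscape

__all__ = [
    "write_raster",
    "read_raster",
    "read_ignitions_csv",
    "write_scenario",
    "load_scenario_dir",
]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

#: raster file names used when a landscape is written as a directory
LANDSCAPE_RASTERS = ("fuel", "moisture", "burn_prob", "elevation",
                     "combustion_rate")


def write_raster(path: str, array: np.ndarray, geometry: GridGeometry,
                 nodata: Optional[float] = None) -> None:
    """Write a single-band float32 GeoTIFF with geo-referencing tags."""
    data = np.asarray(array, dtype=np.float32)
    if data.shape != geometry.shape:
        raise ValueError(f"array shape {data.shape} does not match geometry "
                         f"{geometry.shape}")
    x0, y0 = geometry.origin
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3,
         (geometry.cell_size, geometry.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
    ]
    if nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, str(nodata)))
    tifffile.imwrite(path, data, extratags=extratags)


def read_raster(path: str
                ) -> Tuple[np.ndarray, GridGeometry, Optional[float]]:
    """Read a single-band GeoTIFF; returns (array, geometry, nodata)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        cell_size = 1.0
        origin = (0.0, 0.0)
        nodata = None
        if _TAG_PIXEL_SCALE in tags:
            sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
            cell_size = float(sx)
            if abs(float(sy) - cell_size) > 1e-9 * max(cell_size, 1.0):
                raise ValueError(f"{path}: non-square pixels are unsupported")
        if _TAG_TIEPOINT in tags:
            tie = tags[_TAG_TIEPOINT].value
            origin = (float(tie[3]), float(tie[4]))
        if _TAG_GDAL_NODATA in tags:
            try:
                nodata = float(tags[_TAG_GDAL_NODATA].value)
            except (TypeError, ValueError):
                nodata = None
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster")
    geometry = GridGeometry(n_rows=data.shape[0], n_cols=data.shape[1],
                            cell_size=cell_size, origin=origin)
    return np.asarray(data, dtype=float), geometry, nodata


def read_ignitions_csv(path: str, geometry: GridGeometry) -> IgnitionSet:
    """Load hot pixels from CSV into an ignition set.

    Accepts ``row``/``col`` grid indices or map coordinates under
    ``x``/``y`` (or ``lon``/``lat``).  An optional ``timestamp`` column
    (ISO-8601) is converted to seconds after the earliest entry.
    """
    frame = pd.read_csv(path)
    cols = {c.lower(): c for c in frame.columns}

    if "row" in cols and "col" in cols:
        rows = frame[cols["row"]].astype(int)
        columns = frame[cols["col"]].astype(int)
    else:
        xkey = cols.get("x") or cols.get("lon")
        ykey = cols.get("y") or cols.get("lat")
        if xkey is None or ykey is None:
            raise ValueError(
                f"{path}: need row/col or x/y (lon/lat) columns, "
                f"found {list(frame.columns)}"
            )
        pairs = [geometry.index_of(float(x), float(y))
                 for x, y in zip(frame[xkey], frame[ykey])]
        rows = pd.Series([r for r, _ in pairs])
        columns = pd.Series([c for _, c in pairs])

    if "time_s" in cols:
        seconds = frame[cols["time_s"]].astype(float)
    elif "timestamp" in cols:
        stamps = pd.to_datetime(frame[cols["timestamp"]])
        seconds = (stamps - stamps.min()).dt.total_seconds()
    else:
        seconds = pd.Series(0.0, index=frame.index)

    entries = [(int(r), int(c), float(t))
               for r, c, t in zip(rows, columns, seconds)]
    return IgnitionSet(entries).validate(geometry)


def write_scenario(directory: str, landscape: Landscape,
                   ignitions: IgnitionSet,
                   extra_rasters: Optional[Dict[str, np.ndarray]] = None
                   ) -> None:
    """Write a landscape + ignition set as a directory of GeoTIFFs + CSV."""
    os.makedirs(directory, exist_ok=True)
    geom = landscape.geometry
    for name in LANDSCAPE_RASTERS:
        write_raster(os.path.join(directory, f"{name}.tif"),
                     getattr(landscape, name), geom)
    for name in ("wind_speed", "wind_direction"):
        value = getattr(landscape, name)
        grid = np.broadcast_to(np.asarray(value, dtype=float), geom.shape)
        write_raster(os.path.join(directory, f"{name}.tif"), grid, geom)
    if landscape.nodata.any():
        write_raster(os.path.join(directory, "nodata.tif"),
                     landscape.nodata.astype(np.float32), geom)
    for name, arr in (extra_rasters or {}).items():
        write_raster(os.path.join(directory, f"{name}.tif"), arr, geom)
    pd.DataFrame(
        [(r, c, t) for r, c, t in ignitions],
        columns=["row", "col", "time_s"],
    ).to_csv(os.path.join(directory, "ignitions.csv"), index=False)


def load_scenario_dir(directory: str) -> Tuple[Landscape, IgnitionSet]:
    """Load a scenario directory written by :func:`write_scenario`."""
    rasters = {}
    geometry = None
    for name in LANDSCAPE_RASTERS + ("wind_speed", "wind_direction"):
        path = os.path.join(directory, f"{name}.tif")
        if not os.path.exists(path):
            raise FileNotFoundError(f"scenario raster missing: {path}")
        data, geom, _ = read_raster(path)
        if geometry is None:
            geometry = geom
        elif geom.shape != geometry.shape:
            raise ValueError(f"{path}: geometry differs from first raster")
        rasters[name] = data
    nodata_path = os.path.join(directory, "nodata.tif")
    nodata = None
    if os.path.exists(nodata_path):
        nodata = read_raster(nodata_path)[0].astype(bool)

    landscape = Landscape(
        geometry=geometry,
        fuel=rasters["fuel"],
        moisture=rasters["moisture"],
        burn_prob=rasters["burn_prob"],
        elevation=rasters["elevation"],
        combustion_rate=rasters["combustion_rate"],
        wind_speed=rasters["wind_speed"],
        wind_direction=rasters["wind_direction"],
        nodata=nodata,
    )
    ign_path = os.path.join(directory, "ignitions.csv")
    if os.path.exists(ign_path):
        ignitions = read_ignitions_csv(ign_path, geometry)
    else:
        ignitions = IgnitionSet([])
    return landscape, ignitions
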