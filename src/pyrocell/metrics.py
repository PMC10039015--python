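"""Post-hoc fire metrics: burned patches, spread speed, Byram intensity.

A fire *patch* is an 8-connected component of cells that ever burned.
Spread speed is the ratio of the distance a front propagated (from its
ignition cell to the farthest reached cell center) to its duration.
Byram fireline intensity is the product In = C * D * S of the fuel
consumption rate, the fuel consumed in a step and the spread speed
(kJ m^-1 s^-1 once D carries a mass-per-area scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .engine import FireOutcome

__all__ = [
    "FirePatch",
    "identify_patches",
    "fire_speed",
    "fire_intensity",
    "intensity_records",
    "patch_summary",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass
class FirePatch:
    """One 8-connected burned patch of a completed run."""

    patch_id: int
    cells: np.ndarray            # (n, 2) array of (row, col)
    ignition_cells: np.ndarray   # (k, 2) seed cells of this patch
    first_step: int
    last_step: int

    @property
    def n_cells(self) -> int:
        return int(self.cells.shape[0])

    def duration_steps(self) -> int:
        return self.last_step - self.first_step


def identify_patches(outcome: FireOutcome) -> List[FirePatch]:
    """Label the ever-burned cells of a run into 8-connected patches."""
    burned = outcome.ever_burned
    labels, n_patches = ndimage.label(burned, structure=_EIGHT_CONNECTED)
    seed_set = set(outcome.seed_cells)
    patches: List[FirePatch] = []
    for pid in range(1, n_patches + 1):
        cells = np.argwhere(labels == pid)
        ign_steps = outcome.ignition_step[cells[:, 0], cells[:, 1]]
        first = int(ign_steps.min())
        ext_steps = outcome.extinction_step[cells[:, 0], cells[:, 1]]
        last = int(max(ext_steps.max(), ign_steps.max()))
        seeds = np.array(
            [rc for rc in cells if (int(rc[0]), int(rc[1])) in seed_set]
        )
        if seeds.size == 0:
            # fall back to the earliest-igniting member(s)
            seeds = cells[ign_steps == first]
        patches.append(
            FirePatch(patch_id=pid, cells=cells, ignition_cells=seeds,
                      first_step=first, last_step=last)
        )
    return patches


def _distance_to_nearest_seed(cells: np.ndarray, seeds: np.ndarray,
                              cell_size: float) -> np.ndarray:
    diff = cells[:, None, :].astype(float) - seeds[None, :, :].astype(float)
    dist = np.sqrt((diff ** 2).sum(axis=2)).min(axis=1)
    return dist * cell_size


def fire_speed(patch: FirePatch, dt_seconds: float, cell_size: float) -> float:
    """Front propagation speed of a patch, m/s.

    The distance propagated is the maximum Euclidean distance from the
    patch's ignition cell (nearest of several) to any member cell
    center; the duration is the burning lifetime of the patch.
    Single-cell or single-step patches propagate nothing and return 0.
    """
    if patch.n_cells <= 1 or patch.duration_steps() <= 0:
        return 0.0
    dist = _distance_to_nearest_seed(patch.cells, patch.ignition_cells,
                                     cell_size)
    return float(dist.max() / (patch.duration_steps() * dt_seconds))


def fire_intensity(consumption_rate: float, fuel_consumed: float,
                   speed: float) -> float:
    """Byram fireline intensity In = C * D * S."""
    return consumption_rate * fuel_consumed * speed


def intensity_records(outcome: FireOutcome,
                      patches: Optional[List[FirePatch]] = None
                      ) -> pd.DataFrame:
    """Per-cell, per-step fire intensity from the run's event log.

    D is the fuel consumed by the cell in the step (times the configured
    mass scale); S is the cell's arrival speed — distance from the
    patch's ignition cell divided by the time to reach it (0 for seed
    cells).  Requires the run to have recorded events.
    """
    if patches is None:
        patches = identify_patches(outcome)
    consume = outcome.events[outcome.events["event"] == "consume"]
    if consume.empty:
        return pd.DataFrame(columns=["step", "row", "col", "C", "D", "S",
                                     "intensity"])

    cell_size = outcome.landscape.geometry.cell_size
    shape = outcome.scar.shape
    speed_map = np.zeros(shape)
    for patch in patches:
        dist = _distance_to_nearest_seed(patch.cells, patch.ignition_cells,
                                         cell_size)
        steps = (outcome.ignition_step[patch.cells[:, 0], patch.cells[:, 1]]
                 - patch.first_step)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(steps > 0, dist / (steps * outcome.dt_seconds), 0.0)
        speed_map[patch.cells[:, 0], patch.cells[:, 1]] = s

    rows = consume["row"].to_numpy()
    cols = consume["col"].to_numpy()
    c = outcome.landscape.combustion_rate[rows, cols]
    d = consume["value"].to_numpy() * outcome.params.mass_scale
    s = speed_map[rows, cols]
    return pd.DataFrame({
        "step": consume["step"].to_numpy(),
        "row": rows,
        "col": cols,
        "C": c,
        "D": d,
        "S": s,
        "intensity": c * d * s,
    })


def patch_summary(outcome: FireOutcome,
                  patches: Optional[List[FirePatch]] = None) -> pd.DataFrame:
    """One row per patch: area (ha), duration (s), speed, peak intensity."""
    if patches is None:
        patches = identify_patches(outcome)
    cell_size = outcome.landscape.geometry.cell_size
    cell_area_ha = cell_size * cell_size / 10_000.0
    records = intensity_records(outcome, patches)
    rows = []
    for patch in patches:
        in_patch = np.zeros(outcome.scar.shape, dtype=bool)
        in_patch[patch.cells[:, 0], patch.cells[:, 1]] = True
        if not records.empty:
            mask = in_patch[records["row"], records["col"]]
            peak = float(records.loc[mask, "intensity"].max()) \
                if mask.any() else 0.0
        else:
            peak = float("nan")
        rows.append({
            "patch_id": patch.patch_id,
            "area_ha": patch.n_cells * cell_area_ha,
            "duration_s": patch.duration_steps() * outcome.dt_seconds,
            "speed_m_s": fire_speed(patch, outcome.dt_seconds, cell_size),
            "max_intensity": peak,
        })
    return pd.DataFrame(rows)
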