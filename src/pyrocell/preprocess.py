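"""Derived input rasters from raw bands and burn history.

Produces the four model inputs that in production come from satellite
processing chains: NDWI-based vegetation moisture, the dry-biomass
(fuel-load) fraction by linear spectral unmixing, the burn probability
as a Bayesian-style product of fuel (prior) and relative historical burn
frequency (conditional), and structural vegetation classes with their
combustion rates from a vegetation-height raster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import lsq_linear

from .params import DEFAULT_COMBUSTION_RATES

__all__ = [
    "EndmemberSet",
    "BurnHistory",
    "ndwi",
    "dry_biomass_fraction",
    "burn_probability",
    "vegetation_class",
]


@dataclass(frozen=True)
class EndmemberSet:
    """Spectral endmembers for (Red, NIR, SWIR) unmixing.

    Each signature is a reflectance triple in [0, 1]; the three must be
    linearly independent for the unmixing system to be solvable.  The
    defaults are synthetic, plausible shapes (green vegetation: strong
    NIR plateau; dry vegetation: elevated SWIR; soil: monotone rise) —
    not calibrated to any sensor.
    """

    green: Tuple[float, float, float] = (0.05, 0.50, 0.20)
    dry: Tuple[float, float, float] = (0.25, 0.35, 0.45)
    soil: Tuple[float, float, float] = (0.30, 0.38, 0.32)

    def matrix(self) -> np.ndarray:
        m = np.column_stack([self.green, self.dry, self.soil]).astype(float)
        if np.linalg.matrix_rank(m) < 3:
            raise ValueError("endmember signatures are linearly dependent")
        return m


@dataclass(frozen=True)
class BurnHistory:
    """Historical burn counts per cell over a window of years."""

    burn_frequency: np.ndarray
    window_years: int = 20

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.burn_frequency) < 0):
            raise ValueError("burn frequencies must be >= 0")


def ndwi(nir: np.ndarray, swir: np.ndarray) -> np.ndarray:
    """Moisture raster from NIR and SWIR reflectances, rescaled to [0, 1].

    Raw NDWI = (NIR - SWIR) / (NIR + SWIR) in [-1, 1]; the affine map
    (x + 1) / 2 brings it to the unit interval every downstream formula
    consumes.  Cells where both bands are zero are undefined -> NaN.
    """
    nir = np.asarray(nir, dtype=float)
    swir = np.asarray(swir, dtype=float)
    if nir.shape != swir.shape:
        raise ValueError("NIR and SWIR bands must be co-registered")
    if np.any(nir < 0) or np.any(swir < 0):
        raise ValueError("reflectances must be >= 0")
    denom = nir + swir
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (nir - swir) / denom
    raw = np.where(denom == 0.0, np.nan, raw)
    return (raw + 1.0) / 2.0


def dry_biomass_fraction(red: np.ndarray, nir: np.ndarray, swir: np.ndarray,
                         endmembers: Optional[EndmemberSet] = None
                         ) -> np.ndarray:
    """Dry-vegetation fraction by constrained linear spectral unmixing.

    Each pixel spectrum (Red, NIR, SWIR) is decomposed into non-negative
    fractions of the green-vegetation, dry-vegetation and soil
    endmembers summing to one; the dry fraction is the fuel-load proxy.
    The sum-to-one constraint is enforced by renormalising the bounded
    least-squares solution.
    """
    endmembers = endmembers or EndmemberSet()
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    swir = np.asarray(swir, dtype=float)
    if not (red.shape == nir.shape == swir.shape):
        raise ValueError("bands must be co-registered")

    m = endmembers.matrix()
    # augmented row enforces the sum-to-one constraint softly, followed
    # by an exact renormalisation of the non-negative solution
    weight = 1e4
    a = np.vstack([m, weight * np.ones(3)])
    out = np.empty(red.shape)
    flat_iter = np.nditer(red, flags=["multi_index"])
    for _ in flat_iter:
        idx = flat_iter.multi_index
        spectrum = np.array([red[idx], nir[idx], swir[idx], weight])
        sol = lsq_linear(a, spectrum, bounds=(0.0, np.inf))
        frac = sol.x
        total = frac.sum()
        out[idx] = frac[1] / total if total > 0 else np.nan
    return out


def burn_probability(fuel: np.ndarray, history: BurnHistory) -> np.ndarray:
    """Burn probability p(B|D) = fuel x relative burn frequency.

    Fuel load acts as the prior and the historical burn frequency,
    normalised by its positive maximum, as the conditional evidence:
    frequently burned, fuel-rich cells score highest.  With no burn
    history anywhere the probability is zero everywhere.
    """
    fuel = np.asarray(fuel, dtype=float)
    freq = np.asarray(history.burn_frequency, dtype=float)
    if fuel.shape != freq.shape:
        raise ValueError("fuel and burn history must be co-registered")
    peak = freq.max()
    if peak <= 0:
        return np.zeros(fuel.shape)
    return fuel * (freq / peak)


def vegetation_class(height: np.ndarray,
                     rates: Optional[Dict[int, float]] = None
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Structural class and combustion-rate rasters from vegetation height.

    Height bins (metres): h = 0 grass (1); 0 < h <= 1 herbaceous (2);
    1 < h <= 2 shrub (3); h > 2 tree (4).  ``rates`` maps class code to
    combustion rate and defaults to the package's synthetic table.
    """
    height = np.asarray(height, dtype=float)
    if np.any(height < 0):
        raise ValueError("vegetation heights must be >= 0")
    rates = rates or DEFAULT_COMBUSTION_RATES
    classes = np.full(height.shape, 4, dtype=np.int8)
    classes[height <= 2.0] = 3
    classes[height <= 1.0] = 2
    classes[height == 0.0] = 1
    rate_raster = np.empty(height.shape)
    for code, rate in rates.items():
        if not (0.0 < rate <= 1.0):
            raise ValueError(f"combustion rate for class {code} must be "
                             f"in (0, 1], got {rate}")
        rate_raster[classes == code] = rate
    return classes, rate_raster
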