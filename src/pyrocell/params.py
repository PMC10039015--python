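"""Model parameters and empirical constants.

All constants that govern fire behaviour are collected in a single
:class:`ModelParams` dataclass so that a run is fully described by
(landscape, ignitions, params, seed).  Defaults keep every regime of the
model (spread, blocking, extinction) reachable on synthetic landscapes;
they are configuration values, not field-calibrated measurements, and
should be overridden when fidelity to a particular fuel complex matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

#: Default combustion (fuel-consumption) rate per vegetation structural
#: class, keyed by class code: 1 grass, 2 herbaceous, 3 shrub, 4 tree.
#: Synthetic defaults spanning (0, 1]; grasses consume fastest.
DEFAULT_COMBUSTION_RATES = {1: 0.9, 2: 0.7, 3: 0.5, 4: 0.3}

#: Vegetation class codes used in classified rasters.
VEG_CLASS_NAMES = {1: "grass", 2: "herbaceous", 3: "shrub", 4: "tree"}

#: Quartic diurnal moisture polynomial (c4, c3, c2, c1, c0), argument in
#: seconds since local midnight.  The intercept 0.9734 is the pre-dawn
#: moisture multiplier.
DEFAULT_MOISTURE_POLY = (-4e-20, 1e-14, -8e-10, 2e-05, 0.9734)


@dataclass(frozen=True)
class ModelParams:
    """Empirical constants of the fire-spread cellular automaton.

    Parameters
    ----------
    alpha : float
        Elevation (slope) constant, per degree of slope angle.  Positive
        values make fire climb: a burning neighbour below the target cell
        amplifies flammability by ``exp(alpha * slope)``.
    cw1, cw2, cw3 : float
        Wind constants: ``cw1`` scales every wind term, ``cw2`` (per m/s)
        controls how fast off-axis wind damps spread, ``cw3`` is the
        wind-speed exponent.
    b1 : float
        Moisture attenuation constant; flammability decays as
        ``exp(-b1 * M)`` with moisture fraction ``M``.
    b2 : int
        Exponent of the moisture term in fuel consumption and extinction,
        restricted to positive even integers so that ``(-b1*M)**b2`` is
        real and equals ``(b1*M)**b2``.
    v1 : float
        Minimum combined-flammability threshold a cell must exceed before
        the stochastic ignition draw takes place.
    v2 : float
        Extinction threshold compared against the extinction probability
        ``pE`` (default rule) or the cell moisture (``extinction_rule =
        "moisture"``).
    ignite_threshold : float
        Probability of the final stochastic ignition test: a uniform draw
        below this value ignites the cell.  Calibrated so that spread on a
        uniform, calm, flat landscape produces a radial front.
    timestep_20m : float
        Cellular-automaton time step in seconds at 20 m cell size; the
        step scales linearly with cell size (constant calibrated front
        speed of one cell per step).
    fuel_floor : float
        Fuel fraction below which a burning cell is declared out of fuel;
        geometric fuel decay never reaches exactly zero.
    moisture_poly : tuple
        Quartic coefficients (c4..c0) of the diurnal moisture multiplier,
        evaluated at seconds since local midnight.
    extinction_rule : str
        ``"pe_threshold"`` — extinguish when ``pE > v2`` (default);
        ``"moisture"`` — extinguish when cell moisture ``M < v2``.
    start_time_s : float
        Simulation clock at step 0, seconds since local midnight.
    mass_scale : float
        Optional fuel mass per unit area used to convert fuel fractions
        into consumed-mass units for intensity reporting.
    rng_seed : int
        Seed of the run's random generator.
    """

    alpha: float = 0.078
    cw1: float = 1.0
    cw2: float = 0.131
    cw3: float = 0.5
    b1: float = 3.0
    b2: int = 2
    v1: float = 0.05
    v2: float = 0.95
    ignite_threshold: float = 0.42
    timestep_20m: float = 38.61
    fuel_floor: float = 1e-3
    moisture_poly: Tuple[float, float, float, float, float] = DEFAULT_MOISTURE_POLY
    extinction_rule: str = "pe_threshold"
    start_time_s: float = 43200.0
    mass_scale: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.ignite_threshold < 1.0):
            raise ValueError(
                f"ignite_threshold must lie in (0, 1), got {self.ignite_threshold}"
            )
        if self.v1 < 0:
            raise ValueError(f"v1 must be >= 0, got {self.v1}")
        if not (0.0 <= self.v2 <= 1.0):
            raise ValueError(f"v2 must lie in [0, 1], got {self.v2}")
        if self.timestep_20m <= 0:
            raise ValueError(f"timestep_20m must be > 0, got {self.timestep_20m}")
        if (
            not isinstance(self.b2, int)
            or isinstance(self.b2, bool)
            or self.b2 <= 0
            or self.b2 % 2 != 0
        ):
            raise ValueError(f"b2 must be a positive even integer, got {self.b2!r}")
        if self.extinction_rule not in ("pe_threshold", "moisture"):
            raise ValueError(
                "extinction_rule must be 'pe_threshold' or 'moisture', "
                f"got {self.extinction_rule!r}"
            )
        if len(self.moisture_poly) != 5:
            raise ValueError("moisture_poly needs exactly five coefficients (c4..c0)")
        if self.fuel_floor < 0:
            raise ValueError("fuel_floor must be >= 0")
        if not (0.0 <= self.start_time_s <= 86400.0):
            raise ValueError("start_time_s must lie in [0, 86400]")

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
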