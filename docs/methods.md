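# Methods

## Model structure

The simulator is a synchronous cellular automaton on a north-up,
row-major raster grid.  Five interacting components are evaluated each
step from the fire map at the start of the step: cell flammability and
ignition, fire extinction, fuel consumption, spread speed/intensity
bookkeeping, and hourly vegetation-moisture adjustment.  All state
changes commit together at the end of the step, so update order within
a step cannot leak information.

### Ignition (five-test cascade)

An unburned cell ignites only if (1) a Moore-8 neighbour is burning,
(2) it holds fuel, (3–4) its combined flammability
fF = p(B|D)·fe·fW·fM exceeds the threshold v1, and (5) a uniform draw
falls below the ignition threshold (default 0.42).  The tests
short-circuit in order; the random draw is only consumed when the
deterministic tests pass (in the vectorised grid path, one full-grid
row-major uniform field is drawn per step instead, which keeps runs
bit-reproducible regardless of which cells are candidates — the
per-cell and grid paths are distributionally identical and are checked
against each other in the tests).

Two structural consequences are worth understanding before using the
model:

* The stochastic threshold caps the local spread rate: wherever fF
  clears v1, the frontier advances at the same expected rate.  Wind,
  slope, fuel and moisture therefore shape fire *by gating* — deciding
  where fF falls below v1 — not by accelerating the front.
* Because diagonal and orthogonal neighbours ignite with the same
  per-step probability, a deterministic automaton would grow square
  scars.  The stochastic test is what keeps fronts statistically
  radial on uniform terrain; over the horizons we simulate (tens of
  steps) the 16-sector max/min radius ratio stays near 1.17.  No
  diagonal time correction is applied; over much longer horizons some
  lattice anisotropy would re-emerge.

### Elevation, wind, moisture effects

* fe = Σ exp(α·∅·A_Δ) over burning neighbours, slope angle ∅ from cell
  centres (√2-corrected horizontal distance for diagonals), A_Δ = +1
  when the burning neighbour is below.  Flat ties take A_Δ = +1 with
  ∅ = 0, contributing a neutral factor of 1 so flat terrain cannot
  bias spread.
* fW sums cw1·exp(cw2·S·(cos D − 1))·S^cw3 per burning neighbour,
  D being the angle between the wind vector (direction blown toward,
  degrees clockwise from grid north) and the neighbour→cell bearing.
  At S = 0 the printed form would zero fW and forbid all calm-air
  spread, contradicting the radial calibration; each calm term instead
  contributes cw1 (calm-neutral rule).
* fM = exp(−b1·M) with M the current cell moisture in [0, 1].

### Extinction and fuel

A burning cell goes out when its fuel drops below the floor ε = 1e−3
(geometric decay never reaches exactly zero), or when
pE = V·exp(−(b1·M)^b2) exceeds v2, with V the cell's combustion rate
(default rule; an alternative `extinction_rule="moisture"` extinguishes
when M < v2 — both rules appear in the literature this model family
descends from, and they are not equivalent, so the choice is exposed).
The exponent b2 is restricted to positive even integers so that
(−b1·M)^b2 is real and equals (b1·M)^b2, keeping both the consumption
factor I = exp(−(b1·M)^b2) and pE monotone decreasing in moisture and
inside (0, 1].

Fuel follows B_t = B_{t−1}·(1 − C·I) on burning cells.  The per-step
consumed amounts telescope exactly to initial-minus-final fuel, which
the tests assert to 1e−10.

### Diurnal moisture

M_t = clamp(P(t)·M·(1 − C·N/100), 0, 1), where P is a quartic in
seconds-since-midnight with coefficients
(−4e−20, 1e−14, −8e−10, 2e−05, 0.9734), M the daily moisture, N the
number of burning neighbours and C the combustion rate.  P stays within
roughly 0.95–1.01 over the day (intercept 0.9734 pre-dawn), and nearby
fire dries the cell by up to 8 % with all neighbours burning.  The
simulation clock starts at noon by default (`start_time_s = 43200`) and
wraps modulo 24 h.

### Time step and speed

Δt = 38.61 s at 20 m cells, scaled linearly with cell size (965.25 s at
500 m): the calibration assumes a constant front speed of one cell per
step, 20 m / 38.61 s ≈ 0.518 m/s.  Fire speed is reported per
8-connected burned patch as the maximum distance from the patch's
ignition cell (nearest of several) to any member cell centre, divided
by the patch's burning duration; with stochastic ignition the realised
front speed is somewhat below the one-cell-per-step bound.  Byram
intensity In = C·D·S is recorded per cell and step with D the fuel
consumed that step (times an optional `mass_scale` in kg·m⁻², default 1
so intensities are in fuel-fraction·m/s units) and S the cell's arrival
speed from the patch ignition point (0 for seed cells).  The distance
convention ("distance propagated") is a design choice; an
area-equivalent-radius alternative was considered and rejected as less
interpretable for elongated wind-driven scars.

## Parameters

| name | default | units | role |
|---|---|---|---|
| alpha | 0.078 | per degree | slope amplification of flammability |
| cw1, cw2, cw3 | 1.0, 0.131, 0.5 | —, per m/s, — | wind scaling, off-axis damping, speed exponent |
| b1 | 3.0 | — | moisture attenuation |
| b2 | 2 | — | moisture exponent in consumption/extinction (positive even) |
| v1 | 0.05 | — | minimum combined flammability |
| v2 | 0.95 | — | extinction threshold on pE |
| ignite_threshold | 0.42 | probability | stochastic ignition rate |
| timestep_20m | 38.61 | s | CA step at 20 m cells |
| fuel_floor | 1e−3 | fraction | out-of-fuel declaration |
| combustion rates | 0.9/0.7/0.5/0.3 | per step | grass/herbaceous/shrub/tree |

alpha and cw2 follow the cellular-automata fire-model family this
design descends from; cw1, cw3, b1, b2, v1, v2 and the per-class
combustion rates are package defaults chosen so that every regime —
calm radial spread, wind/slope gating, extinction by fuel exhaustion
and by moisture — is reachable on synthetic landscapes.  They are not
field calibrations; users modelling a real fuel complex must supply
their own values (all are plain config fields).

## Preprocessing

NDWI moisture is (NIR−SWIR)/(NIR+SWIR) affinely rescaled from [−1, 1]
to [0, 1] via (x+1)/2, since every downstream formula consumes moisture
on the unit interval; the rescaling choice is ours.  The dry-biomass
fraction comes from constrained linear unmixing of (Red, NIR, SWIR)
onto green-vegetation/dry-vegetation/soil endmembers (non-negative
fractions, sum to one, solved by bounded least squares with a strongly
weighted sum constraint and exact renormalisation); the default
endmembers are synthetic triples, not sensor calibrations.  Burn
probability is realised as fuel × (burn frequency / max positive
frequency) — a normalised-product reading of a fuel-prior ×
frequency-conditional construction; the function is pluggable.
Vegetation classes bin height as grass (h = 0), herbaceous (0 < h ≤ 1),
shrub (1 < h ≤ 2), tree (h > 2) and map to combustion rates from
configuration.

## Monte Carlo mode

Per run, one truncated-normal offset per variable (wind speed,
direction, fuel, moisture) is applied to the whole raster — the
observation systems err on regional levels rather than per pixel; an
independent per-cell-noise option exists but is off by default.
Offsets are truncated (not clipped) so distributions stay proper and no
cell leaves its legal range; wind direction wraps modulo 360 instead.
Ignition counts are Poisson with an optional spatial placement weight.
A master seed spawns per-run child seeds through `SeedSequence`, so
ensembles are reproducible and runs mutually independent.  The map mean
equals the mean burned fraction across runs by construction, and its
cell-wise standard error shrinks as 1/√n.

## Validation metrics

The comparison region is the union of the bounding boxes of the
observed and simulated scars (default), which removes the unchanged
background while keeping a true-negative population so that accuracy
does not collapse into an overlap coefficient; a strict
union-of-burned-masks variant is available.  Reciprocal similarity
fuzzifies each map with an exponential decay of distance-to-nearest-burn
(half-distance 2 cells by default, window radius 4 half-distances —
both free choices, exposed as arguments), scores each map's burned
cells against the other's fuzzy surface, and returns the minimum of the
two directional means, so over- and underprediction both depress the
score.  AUC is the rank-based (Mann–Whitney) form with ties counted
half.  The null model reruns the engine with fuel replaced by its
spatial mean and wind forced calm, leaving everything else (including
the seed) unchanged.

## Synthetic landscapes

`gen_field` builds constant fields or Gaussian-smoothed white noise
rescaled to a requested range — the simplest controllable spatial
autocorrelation.  This emulates only the qualitative patchiness of
satellite-derived inputs: no sensor noise, no cloud artefacts, no
anisotropic terrain-driven correlation.  Passing tests on these
landscapes demonstrates the mechanics of the model, not predictive
skill on real fires.

Named scenarios pin interpretable regimes.  `radial` (uniform fuel 1.0,
moisture 0.2, burn probability 1.0, flat, calm) is the calibration
configuration for radial fronts.  `wind_ellipse` (moisture 0.5, burn
probability 0.6, 10 m/s wind) puts single-neighbour upwind flammability
just below v1 and downwind well above, so scars elongate downwind.
`slope` (30° incline, calm) does the same for downslope spread.
`firebreak` inserts a zero-fuel stripe the fire cannot cross.  `patchy`
(correlated fuel in [0.2, 1.0], moisture ≈ 0.5, burn probability
0.45 × fuel, 10 m/s wind) is deliberately constructed in the wind-gated
regime: calm spread sits at the v1 threshold, so both the wind boost
and the fuel-rich corridors carry real predictive information.  That
construction is what makes the null-model comparison meaningful — with
spread rate capped by the stochastic threshold, a scenario where calm
spread passes v1 everywhere lets the ungated null cover a superset of
any gated run and trivially win on sensitivity, which is a degenerate
property of the metric (it rewards overprediction), not evidence about
the model.

## Numerical choices and degenerate inputs

* Flat elevation ties: neutral (A_Δ = +1, ∅ = 0).
* Nodata cells: fuel forced to 0; they never ignite, including from
  hot pixels.
* Hot pixels ignite unconditionally when the clock reaches their
  timestamp, but only while the cell still holds fuel (a burning state
  requires fuel at ignition).
* Empty ignition sets warn and return an empty scar rather than
  raising.
* A run stops early once no cell is burning and no ignition is
  pending.
* Forward-dating of inputs multiplies fuel and moisture by
  1 + trend(days) with linear default trends (+0.005/day fuel curing,
  −0.01/day moisture drying), clamps to [0, 1], and refuses horizons
  beyond 20 days — past that the projection is not trusted.
* GeoTIFF I/O uses the standard ModelPixelScale/ModelTiepoint/GDAL
  nodata tags via `tifffile`; only square-pixel, single-band rasters
  are supported, and no reprojection or resampling is attempted —
  inputs must be co-registered.

## Problem sizes used by the test suite

The suite exercises grids from 5×5 (exact oracle comparisons against a
naive per-cell transcription of the model equations) through 121×121
(radial-front statistics, 30 seeds × 55 steps), and Monte Carlo
ensembles of 4 × 50 and 4 × 200 runs on a 25×25 grid for the 1/√n
convergence check.  These sizes give stable statistics for every
property tested while keeping the full suite fast; all stochastic tests
fix their seeds.

## Known limitations

* No ember spotting, crown fire, atmosphere–fire coupling or
  suppression actions.
* Spread rate is capped by the stochastic ignition threshold; the
  model cannot represent wind-accelerated fronts faster than one cell
  per step.
* Default constants are synthetic-regime defaults, not field
  calibrations (see Parameters).
* The comparison-region and similarity-kernel parameters are
  conventions; reported similarity values are only comparable between
  runs using the same settings.
* Per-run Monte Carlo offsets are spatially uniform; real forecast
  errors have spatial structure the default does not model.
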