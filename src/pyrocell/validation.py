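"""Map-comparison validation of simulated fire scars.

Metrics compare a simulated scar (or probability surface) against an
observed burned-area map inside a comparison region formed from the
union of the two fires' extents, which removes the vast unchanged
background that would otherwise inflate agreement:

* reciprocal similarity — fuzzy agreement with exponential distance
  decay, computed in both directions and reduced by the minimum;
* accuracy and sensitivity — overall hit rate and presence hit rate
  from the confusion counts;
* AUC — rank-based probability that a burned cell outranks an unburned
  one on the probability surface, ties counted half;
* null model — a baseline run with constant fuel and no wind.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import ndimage, stats

from .engine import FireOutcome, run_simulation
from .landscape import IgnitionSet, Landscape
from .montecarlo import BurnProbabilityMap
from .params import ModelParams

__all__ = [
    "ComparisonResult",
    "comparison_region",
    "confusion_metrics",
    "reciprocal_similarity",
    "auc",
    "null_model_run",
    "compare_scars",
]


@dataclass
class ComparisonResult:
    """Confusion counts and the derived agreement scores."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    sensitivity: float
    reciprocal_similarity: Optional[float] = None
    mask: Optional[np.ndarray] = None


def _bbox_mask(scar: np.ndarray) -> np.ndarray:
    mask = np.zeros(scar.shape, dtype=bool)
    rows, cols = np.nonzero(scar)
    if rows.size:
        mask[rows.min():rows.max() + 1, cols.min():cols.max() + 1] = True
    return mask


def comparison_region(observed: np.ndarray, simulated: np.ndarray,
                      mode: str = "bbox_union") -> np.ndarray:
    """Comparison mask from the union of the two fires' extents.

    ``bbox_union`` (default) unions the minimal bounding boxes of the
    two scars, which keeps an unburned population near the fires so that
    accuracy is not reduced to a pure overlap score; ``mask_union``
    restricts strictly to cells burned in either map.
    """
    observed = np.asarray(observed, dtype=bool)
    simulated = np.asarray(simulated, dtype=bool)
    if observed.shape != simulated.shape:
        raise ValueError("observed and simulated scars must be co-registered")
    if not observed.any() and not simulated.any():
        raise ValueError("both scars are empty: no comparison region")
    if mode == "bbox_union":
        return _bbox_mask(observed) | _bbox_mask(simulated)
    if mode == "mask_union":
        return observed | simulated
    raise ValueError(f"unknown comparison-region mode {mode!r}")


def confusion_metrics(observed: np.ndarray, simulated: np.ndarray,
                      mask: np.ndarray) -> ComparisonResult:
    """Confusion counts, accuracy and sensitivity inside the mask."""
    if not mask.any():
        raise ValueError("empty comparison mask")
    obs = np.asarray(observed, dtype=bool)[mask]
    sim = np.asarray(simulated, dtype=bool)[mask]
    tp = int(np.count_nonzero(obs & sim))
    fp = int(np.count_nonzero(~obs & sim))
    fn = int(np.count_nonzero(obs & ~sim))
    tn = int(np.count_nonzero(~obs & ~sim))
    total = tp + fp + fn + tn
    accuracy = (tp + tn) / total if total else 0.0
    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    return ComparisonResult(tp=tp, fp=fp, fn=fn, tn=tn,
                            accuracy=accuracy, sensitivity=sensitivity,
                            mask=mask)


def _fuzzy_membership(scar: np.ndarray, half_distance: float,
                      window_factor: float) -> np.ndarray:
    """Per-cell fuzzy burned membership: exponential decay of the
    distance (in cells) to the nearest burned cell, zero beyond the
    search window.  The nearest burned cell dominates because the decay
    kernel is monotone."""
    if not scar.any():
        return np.zeros(scar.shape)
    dist = ndimage.distance_transform_edt(~scar)
    membership = np.exp(-np.log(2.0) * dist / half_distance)
    membership[dist > window_factor * half_distance] = 0.0
    return membership


def reciprocal_similarity(observed: np.ndarray, simulated: np.ndarray,
                          mask: np.ndarray, half_distance: float = 2.0,
                          window_factor: float = 4.0) -> float:
    """Two-way fuzzy map agreement with exponential decay.

    Each map is compared against a fuzzified version of the other: a
    burned cell scores the fuzzy membership of the opposite map at its
    location (1 at zero offset, 1/2 at ``half_distance`` cells, 0 beyond
    the search window).  Direction scores are the means over burned
    cells; the reciprocal rule returns the minimum of the two, so
    overprediction and underprediction both depress the score.
    """
    obs = np.asarray(observed, dtype=bool) & mask
    sim = np.asarray(simulated, dtype=bool) & mask

    def _direction(a: np.ndarray, b: np.ndarray) -> float:
        if not a.any():
            return 0.0
        fuzzy_b = _fuzzy_membership(b, half_distance, window_factor)
        return float(fuzzy_b[a].mean())

    return min(_direction(obs, sim), _direction(sim, obs))


def auc(probability: Union[BurnProbabilityMap, np.ndarray],
        observed: np.ndarray, mask: np.ndarray) -> float:
    """Rank-based AUC of a burn-probability surface against a scar.

    Equals the probability that a uniformly chosen burned cell carries a
    higher probability value than an unburned one, ties counted half
    (Mann-Whitney form); invariant under strictly monotone transforms
    of the probability values.
    """
    if isinstance(probability, BurnProbabilityMap):
        probability = probability.probability
    scores = np.asarray(probability, dtype=float)[mask]
    labels = np.asarray(observed, dtype=bool)[mask]
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: only one class inside the mask")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def null_model_run(landscape: Landscape, ignitions: IgnitionSet,
                   horizon_hours: float,
                   params: Optional[ModelParams] = None,
                   n_steps: Optional[int] = None) -> FireOutcome:
    """Baseline run with constant fuel (spatial mean) and no wind.

    Everything else — moisture, burn probability, elevation, combustion
    rates, the ignition set and the seed — is left unchanged, so the
    difference to a full run isolates the predictive value of the fuel
    and wind inputs.
    """
    null_landscape = landscape.copy()
    valid = ~null_landscape.nodata
    null_landscape.fuel = np.where(
        valid, float(landscape.fuel[valid].mean()), 0.0)
    null_landscape.wind_speed = 0.0
    return run_simulation(null_landscape, ignitions, horizon_hours,
                          params, n_steps=n_steps, record_events=False)


def compare_scars(observed: np.ndarray, simulated: np.ndarray,
                  half_distance: float = 2.0,
                  region_mode: str = "bbox_union") -> ComparisonResult:
    """Convenience wrapper: region, confusion metrics and similarity."""
    mask = comparison_region(observed, simulated, mode=region_mode)
    result = confusion_metrics(observed, simulated, mask)
    result.reciprocal_similarity = reciprocal_similarity(
        observed, simulated, mask, half_distance=half_distance)
    return result
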