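import math

import numpy as np
import pytest

from pyrocell import ModelParams, gen_scenario, run_simulation
from pyrocell.validation import (auc, compare_scars, comparison_region,
                                 confusion_metrics, null_model_run,
                                 reciprocal_similarity)


def _scar(shape, cells):
    arr = np.zeros(shape, dtype=bool)
    for cell in cells:
        arr[cell] = True
    return arr


class TestComparisonRegion:
    def test_identical_scars_region_is_bbox(self):
        scar = _scar((10, 10), [(2, 2), (4, 5)])
        mask = comparison_region(scar, scar)
        expected = np.zeros((10, 10), dtype=bool)
        expected[2:5, 2:6] = True
        assert np.array_equal(mask, expected)

    def test_disjoint_scars_union_of_boxes(self):
        obs = _scar((10, 10), [(1, 1)])
        sim = _scar((10, 10), [(8, 8)])
        mask = comparison_region(obs, sim)
        assert mask[1, 1] and mask[8, 8]
        assert mask.sum() == 2

    def test_nested_boxes_take_the_larger(self):
        obs = np.zeros((20, 20), dtype=bool)
        obs[0:10, 0:10] = True       # 10x10 box
        sim = np.zeros((20, 20), dtype=bool)
        sim[3:8, 3:8] = True         # 5x5 inside it
        mask = comparison_region(obs, sim)
        assert mask.sum() == 100

    def test_strict_mask_union_variant(self):
        obs = _scar((10, 10), [(1, 1), (1, 3)])
        sim = _scar((10, 10), [(1, 2)])
        mask = comparison_region(obs, sim, mode="mask_union")
        assert mask.sum() == 3

    def test_both_empty_raises(self):
        empty = np.zeros((5, 5), dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            comparison_region(empty, empty)


class TestConfusionMetrics:
    def test_perfect_agreement(self):
        scar = _scar((8, 8), [(2, 2), (3, 3), (2, 3)])
        mask = comparison_region(scar, scar)
        result = confusion_metrics(scar, scar, mask)
        assert result.accuracy == 1.0 and result.sensitivity == 1.0
        assert result.fp == 0 and result.fn == 0

    def test_complement_has_zero_accuracy(self):
        mask = np.ones((4, 4), dtype=bool)
        obs = np.zeros((4, 4), dtype=bool)
        obs[:2] = True
        sim = ~obs
        result = confusion_metrics(obs, sim, mask)
        assert result.accuracy == 0.0

    def test_toy_counts(self):
        # 4x4 mask with TP=6, FP=2, FN=2, TN=6
        mask = np.ones((4, 4), dtype=bool)
        obs = np.zeros((4, 4), dtype=bool)
        sim = np.zeros((4, 4), dtype=bool)
        obs.flat[:8] = True
        sim.flat[2:10] = True
        result = confusion_metrics(obs, sim, mask)
        assert (result.tp, result.fp, result.fn, result.tn) == (6, 2, 2, 6)
        assert result.accuracy == 0.75
        assert result.sensitivity == 0.75

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.random((10, 10)) < 0.4
        sim = rng.random((10, 10)) < 0.4
        mask = rng.random((10, 10)) < 0.7
        if not mask.any():
            mask[0, 0] = True
        result = confusion_metrics(obs, sim, mask)
        tp = fp = fn = tn = 0
        for r in range(10):
            for c in range(10):
                if not mask[r, c]:
                    continue
                if obs[r, c] and sim[r, c]:
                    tp += 1
                elif sim[r, c]:
                    fp += 1
                elif obs[r, c]:
                    fn += 1
                else:
                    tn += 1
        assert (result.tp, result.fp, result.fn, result.tn) == (tp, fp, fn,
                                                                tn)


def _brute_similarity(obs, sim, mask, half_distance, window_factor=4.0):
    """Double-loop transcription of the fuzzy reciprocal comparison."""
    def fuzzy(target, r, c):
        best = 0.0
        cells = np.argwhere(target)
        for rr, cc in cells:
            d = math.hypot(r - rr, c - cc)
            if d <= window_factor * half_distance:
                best = max(best,
                           math.exp(-math.log(2.0) * d / half_distance))
        return best

    def direction(a, b):
        cells = np.argwhere(a & mask)
        if cells.size == 0:
            return 0.0
        return float(np.mean([fuzzy(b & mask, r, c) for r, c in cells]))

    return min(direction(obs, sim), direction(sim, obs))


class TestReciprocalSimilarity:
    def test_identical_maps_score_one(self):
        scar = _scar((10, 10), [(3, 3), (3, 4), (4, 4)])
        mask = comparison_region(scar, scar)
        assert reciprocal_similarity(scar, scar, mask) == 1.0

    def test_empty_simulated_scores_zero(self):
        obs = _scar((10, 10), [(3, 3)])
        sim = np.zeros((10, 10), dtype=bool)
        mask = comparison_region(obs, sim)
        assert reciprocal_similarity(obs, sim, mask) == 0.0

    def test_one_cell_offset_matches_brute_force(self):
        obs = _scar((12, 12), [(5, 5), (5, 6), (6, 5)])
        sim = _scar((12, 12), [(5, 6), (5, 7), (6, 6)])
        mask = np.ones((12, 12), dtype=bool)
        for half in (1.0, 2.0, 5.0):
            assert reciprocal_similarity(obs, sim, mask, half) == \
                pytest.approx(_brute_similarity(obs, sim, mask, half),
                              abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_scars_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.random((9, 9)) < 0.25
        sim = rng.random((9, 9)) < 0.25
        if not obs.any():
            obs[4, 4] = True
        if not sim.any():
            sim[5, 5] = True
        mask = np.ones((9, 9), dtype=bool)
        assert reciprocal_similarity(obs, sim, mask, 2.0) == pytest.approx(
            _brute_similarity(obs, sim, mask, 2.0), abs=1e-12)

    def test_symmetric_under_argument_swap(self):
        rng = np.random.default_rng(7)
        obs = rng.random((10, 10)) < 0.3
        sim = rng.random((10, 10)) < 0.3
        mask = np.ones((10, 10), dtype=bool)
        assert reciprocal_similarity(obs, sim, mask) == \
            reciprocal_similarity(sim, obs, mask)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            obs = rng.random((8, 8)) < 0.3
            sim = rng.random((8, 8)) < 0.3
            mask = np.ones((8, 8), dtype=bool)
            value = reciprocal_similarity(obs, sim, mask)
            assert 0.0 <= value <= 1.0


class TestAuc:
    def test_perfect_separator(self):
        prob = np.array([[0.9, 0.8], [0.2, 0.1]])
        obs = np.array([[True, True], [False, False]])
        mask = np.ones((2, 2), dtype=bool)
        assert auc(prob, obs, mask) == 1.0

    def test_constant_scores_give_half(self):
        prob = np.full((2, 3), 0.4)
        obs = np.array([[True, False, True], [False, False, True]])
        mask = np.ones((2, 3), dtype=bool)
        assert auc(prob, obs, mask) == 0.5

    def test_six_cell_toy_is_eight_ninths(self):
        prob = np.array([[0.9, 0.8, 0.4, 0.7, 0.3, 0.1]])
        obs = np.array([[True, True, True, False, False, False]])
        mask = np.ones((1, 6), dtype=bool)
        assert auc(prob, obs, mask) == pytest.approx(8.0 / 9.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        prob = rng.random((6, 6))
        obs = rng.random((6, 6)) < 0.4
        obs[0, 0] = True
        obs[0, 1] = False
        mask = np.ones((6, 6), dtype=bool)
        base = auc(prob, obs, mask)
        assert auc(prob ** 3, obs, mask) == pytest.approx(base)
        assert auc(np.log(prob + 1e-9), obs, mask) == pytest.approx(base)

    def test_single_class_flagged(self):
        prob = np.random.default_rng(0).random((3, 3))
        obs = np.ones((3, 3), dtype=bool)
        with pytest.raises(ValueError, match="one class"):
            auc(prob, obs, np.ones((3, 3), dtype=bool))


class TestNullModel:
    def test_homogeneous_landscape_null_equals_full(self):
        ls, ign = gen_scenario("radial", n_rows=31, n_cols=31)
        params = ModelParams(rng_seed=4)
        full = run_simulation(ls, ign, 0.3, params, record_events=False)
        null = null_model_run(ls, ign, 0.3, params)
        assert np.array_equal(full.scar, null.scar)

    def test_heterogeneous_fuel_changes_the_scar(self):
        ls, ign = gen_scenario("patchy", n_rows=41, n_cols=41)
        params = ModelParams(rng_seed=4)
        full = run_simulation(ls, ign, 0.3, params, record_events=False)
        null = null_model_run(ls, ign, 0.3, params)
        assert not np.array_equal(full.scar, null.scar)

    def test_null_model_is_calm_and_uniform(self):
        ls, ign = gen_scenario("patchy", n_rows=21, n_cols=21)
        null = null_model_run(ls, ign, 0.1, ModelParams(rng_seed=0))
        assert float(null.landscape.wind_speed) == 0.0
        assert np.ptp(null.landscape.fuel) == 0.0
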