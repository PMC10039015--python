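import math

import numpy as np
import pytest

from pyrocell import ModelParams, timestep_for_resolution
from pyrocell.engine import (BURNING, FireState, combined_flammability,
                             elevation_effect, extinction_test, fuel_update,
                             hourly_moisture, ignition_test,
                             moisture_effect, moisture_flammability_factor,
                             wind_effect)
from pyrocell.landscape import neighbor_context

from naive_oracle import naive_polynomial


def _context(landscape, burning_cells):
    fire = np.zeros(landscape.geometry.shape, dtype=bool)
    for cell in burning_cells:
        fire[cell] = True
    return neighbor_context(landscape, fire, 2, 2)


class TestElevationEffect:
    def test_no_burning_neighbors_is_zero(self, flat_landscape):
        ctx = _context(flat_landscape, [])
        assert elevation_effect(ctx, alpha=0.078) == 0.0

    def test_flat_burning_neighbor_contributes_one(self, flat_landscape):
        ctx = _context(flat_landscape, [(1, 2)])
        assert elevation_effect(ctx, alpha=0.078) == pytest.approx(1.0)

    def test_neighbor_below_at_30_degrees(self, flat_landscape):
        # neighbour 30 degrees below the centre: fe = exp(0.078*30)
        flat_landscape.elevation[2, 2] = 20.0 * math.tan(math.radians(30.0))
        ctx = _context(flat_landscape, [(1, 2)])
        assert elevation_effect(ctx, alpha=0.078) == pytest.approx(
            math.exp(2.34), rel=1e-6)
        assert math.exp(2.34) == pytest.approx(10.381, abs=5e-3)

    def test_neighbor_above_damps(self, flat_landscape):
        flat_landscape.elevation[1, 2] = 20.0
        ctx = _context(flat_landscape, [(1, 2)])
        assert elevation_effect(ctx, alpha=0.078) == pytest.approx(
            math.exp(-0.078 * 45.0))

    def test_sums_over_burning_neighbors(self, flat_landscape):
        ctx = _context(flat_landscape, [(1, 2), (3, 2), (2, 1)])
        assert elevation_effect(ctx, alpha=0.078) == pytest.approx(3.0)


class TestWindEffect:
    def test_no_burning_neighbors_is_zero(self, flat_landscape):
        ctx = _context(flat_landscape, [])
        assert wind_effect(ctx, 5.0, 0.0, 1.0, 0.131, 0.5) == 0.0

    def test_aligned_wind_leaves_speed_term(self, flat_landscape):
        # burning neighbour south of centre -> spread bearing 0 (north);
        # wind blowing toward north (0 deg): exponent vanishes
        ctx = _context(flat_landscape, [(3, 2)])
        fw = wind_effect(ctx, 9.0, 0.0, 1.0, 0.131, 0.5)
        assert fw == pytest.approx(9.0 ** 0.5)

    def test_opposed_wind_damps(self, flat_landscape):
        ctx = _context(flat_landscape, [(3, 2)])
        fw = wind_effect(ctx, 9.0, 180.0, 1.0, 0.131, 0.5)
        assert fw == pytest.approx(
            math.exp(0.131 * 9.0 * (-2.0)) * 9.0 ** 0.5)
        assert fw < wind_effect(ctx, 9.0, 0.0, 1.0, 0.131, 0.5)

    def test_calm_neighbor_contributes_cw1(self, flat_landscape):
        ctx = _context(flat_landscape, [(3, 2), (1, 2)])
        assert wind_effect(ctx, 0.0, 0.0, 1.3, 0.131, 0.5) == pytest.approx(
            2.6)


class TestMoistureAndCombination:
    def test_dry_cell_moisture_effect_is_one(self):
        assert moisture_effect(0.0, 3.0) == 1.0

    def test_moisture_effect_value(self):
        assert moisture_effect(0.5, 3.0) == pytest.approx(
            math.exp(-1.5), rel=1e-9)
        assert math.exp(-1.5) == pytest.approx(0.22313, abs=1e-5)

    def test_moisture_effect_strictly_decreasing(self):
        values = [moisture_effect(m, 3.0) for m in np.linspace(0, 1, 11)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_combined_flammability_is_product(self):
        assert combined_flammability(0.8, 1.2, 0.9, 0.5) == pytest.approx(
            0.432)
        assert combined_flammability(0.0, 9.0, 9.0, 1.0) == 0.0
        assert combined_flammability(1.0, 1.0, 1.0, 1.0) == 1.0


class TestFuelDynamics:
    def test_factor_one_when_dry(self):
        assert moisture_flammability_factor(0.0, 3.0, 2) == 1.0

    def test_factor_value(self):
        # I = exp(-(3*0.5)**2) = exp(-2.25)
        assert moisture_flammability_factor(0.5, 3.0, 2) == pytest.approx(
            math.exp(-2.25), rel=1e-9)
        assert math.exp(-2.25) == pytest.approx(0.10540, abs=1e-5)

    def test_factor_monotone_decreasing(self):
        values = [moisture_flammability_factor(m, 3.0, 2)
                  for m in np.linspace(0, 1, 11)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_fuel_update_no_consumption(self):
        assert fuel_update(0.7, 0.0, 1.0) == 0.7

    def test_fuel_update_half(self):
        assert fuel_update(1.0, 0.5, 1.0) == pytest.approx(0.5)

    def test_repeated_update_decays_geometrically_never_zero(self):
        fuel = 1.0
        for _ in range(200):
            fuel = fuel_update(fuel, 0.5, 0.8)
            assert fuel > 0.0
        assert fuel == pytest.approx((1 - 0.4) ** 200)


class TestExtinction:
    def test_out_of_fuel_always_extinguishes(self, params):
        out, _ = extinction_test(0.0, 0.2, 0.9, params)
        assert out

    def test_pe_threshold_rule(self):
        params = ModelParams(v2=0.95)
        # V=0.9, M=0 -> pE = 0.9 < 0.95 -> keeps burning
        out, pe = extinction_test(1.0, 0.0, 0.9, params)
        assert not out
        assert pe == pytest.approx(0.9)
        # lower threshold -> extinguishes
        out, _ = extinction_test(1.0, 0.0, 0.9, ModelParams(v2=0.5))
        assert out

    def test_moisture_rule_variant(self):
        params = ModelParams(extinction_rule="moisture", v2=0.3)
        assert extinction_test(1.0, 0.2, 0.9, params)[0]       # M < v2
        assert not extinction_test(1.0, 0.5, 0.9, params)[0]   # M >= v2


class TestHourlyMoisture:
    def test_midnight_intercept(self):
        assert hourly_moisture(1.0, 0.0, 0, 0.9,
                               ModelParams().moisture_poly) == 0.9734

    def test_no_fire_no_adjustment_factor(self):
        coeffs = ModelParams().moisture_poly
        m_no_fire = hourly_moisture(0.5, 3600.0, 0, 0.9, coeffs)
        assert m_no_fire == pytest.approx(
            naive_polynomial(coeffs, 3600.0) * 0.5, rel=1e-12)

    def test_matches_polynomial_oracle_at_noon(self):
        coeffs = ModelParams().moisture_poly
        expected = naive_polynomial(coeffs, 43200.0) * 0.5
        assert hourly_moisture(0.5, 43200.0, 0, 0.9, coeffs) == \
            pytest.approx(expected, rel=1e-12)

    def test_nearby_fire_dries_the_cell(self):
        coeffs = ModelParams().moisture_poly
        base = hourly_moisture(0.5, 43200.0, 0, 0.9, coeffs)
        burnt = hourly_moisture(0.5, 43200.0, 8, 0.9, coeffs)
        assert burnt == pytest.approx(base * (1 - 0.9 * 8 / 100.0))

    def test_time_outside_day_rejected(self):
        with pytest.raises(ValueError):
            hourly_moisture(0.5, -1.0, 0, 0.9, ModelParams().moisture_poly)
        with pytest.raises(ValueError):
            hourly_moisture(0.5, 90000.0, 0, 0.9, ModelParams().moisture_poly)


class TestTimestep:
    @pytest.mark.parametrize("cell_size,expected", [
        (20.0, 38.61), (500.0, 965.25), (100.0, 193.05)])
    def test_linear_scaling(self, cell_size, expected, params):
        assert timestep_for_resolution(cell_size, params) == expected

    def test_non_positive_size_rejected(self, params):
        with pytest.raises(ValueError):
            timestep_for_resolution(0.0, params)


class TestIgnitionTest:
    def _state(self, landscape, params, burning=()):
        state = FireState.initial(landscape, params)
        for cell in burning:
            state.status[cell] = BURNING
        return state

    def test_no_burning_neighbor_short_circuits(self, flat_landscape,
                                                params):
        state = self._state(flat_landscape, params)
        rng = np.random.default_rng(0)
        ignites, result = ignition_test(state, 2, 2, flat_landscape, params,
                                        rng)
        assert not ignites and result is None

    def test_zero_fuel_blocks(self, flat_landscape, params):
        state = self._state(flat_landscape, params, burning=[(1, 2)])
        state.fuel[2, 2] = 0.0
        rng = np.random.default_rng(0)
        ignites, result = ignition_test(state, 2, 2, flat_landscape, params,
                                        rng)
        assert not ignites and result is None

    def test_below_v1_blocks_without_drawing(self, flat_landscape, params):
        state = self._state(flat_landscape, params, burning=[(1, 2)])
        high_v1 = params.with_(v1=1e6)
        rng = np.random.default_rng(0)
        before = rng.bit_generator.state
        ignites, result = ignition_test(state, 2, 2, flat_landscape, high_v1,
                                        rng)
        assert not ignites and result is not None
        assert rng.bit_generator.state == before  # no draw consumed

    def test_draw_decides_at_the_threshold(self, flat_landscape, params):
        state = self._state(flat_landscape, params, burning=[(1, 2)])

        class FixedRng:
            def __init__(self, u):
                self.u = u

            def random(self):
                return self.u

        assert ignition_test(state, 2, 2, flat_landscape, params,
                             FixedRng(0.41))[0]
        assert not ignition_test(state, 2, 2, flat_landscape, params,
                                 FixedRng(0.43))[0]

    def test_flammability_decomposition_consistent(self, flat_landscape,
                                                   params):
        state = self._state(flat_landscape, params, burning=[(1, 2), (3, 2)])
        rng = np.random.default_rng(0)
        _, result = ignition_test(state, 2, 2, flat_landscape, params, rng)
        assert result.n_burning_neighbors == 2
        assert result.ff == pytest.approx(
            flat_landscape.burn_prob[2, 2] * result.fe * result.fw
            * result.fm, rel=1e-12)
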