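"""Naive per-cell reference implementation of the flammability, fuel and
extinction equations: direct formula transcription with explicit loops,
independent of the engine's vectorised path and of the landscape
module's neighbourhood helper."""

import math

import numpy as np

OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0),
           (1, 1)]


def naive_bearing(dr, dc):
    """Bearing from the neighbour at (dr, dc) toward the centre,
    degrees clockwise from north on a north-up grid."""
    return math.degrees(math.atan2(-dc, dr)) % 360.0


def naive_flammability(elevation, fire, moisture, burn_prob, wind_speed,
                       wind_direction, cell_size, alpha, cw1, cw2, cw3, b1):
    """fe, fW, fM, fF grids computed cell by cell with explicit loops."""
    n, m = elevation.shape
    fe = np.zeros((n, m))
    fw = np.zeros((n, m))
    fm = np.zeros((n, m))
    ff = np.zeros((n, m))
    for r in range(n):
        for c in range(m):
            fe_sum = 0.0
            fw_sum = 0.0
            for dr, dc in OFFSETS:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < n and 0 <= cc < m):
                    continue
                if not fire[rr, cc]:
                    continue
                dz = elevation[rr, cc] - elevation[r, c]
                dist = cell_size * math.sqrt(dr * dr + dc * dc)
                phi = math.degrees(math.atan(abs(dz) / dist))
                a_delta = -1.0 if dz > 0 else 1.0
                fe_sum += math.exp(alpha * phi * a_delta)
                s = wind_speed
                if s <= 0:
                    fw_sum += cw1
                else:
                    d = math.radians(wind_direction - naive_bearing(dr, dc))
                    fw_sum += (cw1 * math.exp(cw2 * s * (math.cos(d) - 1.0))
                               * s ** cw3)
            fe[r, c] = fe_sum
            fw[r, c] = fw_sum
            fm[r, c] = math.exp(-b1 * moisture[r, c])
            ff[r, c] = burn_prob[r, c] * fe_sum * fw_sum * fm[r, c]
    return fe, fw, fm, ff


def naive_fuel_and_extinction(fuel, moisture, rate, fire, b1, b2, v2,
                              fuel_floor):
    """One step of fuel consumption and the extinction decision, looped."""
    n, m = fuel.shape
    new_fuel = fuel.copy()
    extinguish = np.zeros((n, m), dtype=bool)
    for r in range(n):
        for c in range(m):
            if not fire[r, c]:
                continue
            i_factor = math.exp(-((b1 * moisture[r, c]) ** b2))
            new_fuel[r, c] = fuel[r, c] - fuel[r, c] * rate[r, c] * i_factor
            pe = rate[r, c] * i_factor
            extinguish[r, c] = fuel[r, c] <= fuel_floor or pe > v2
    return new_fuel, extinguish


def naive_polynomial(coeffs, t):
    """Quartic evaluated term by term (c4, c3, c2, c1, c0)."""
    c4, c3, c2, c1, c0 = coeffs
    return c4 * t ** 4 + c3 * t ** 3 + c2 * t ** 2 + c1 * t + c0
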