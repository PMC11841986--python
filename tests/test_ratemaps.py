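"""Occupancy, rate maps, and spatial autocorrelograms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gridvar.io_core import Recording
from gridvar.ratemaps import (
    RateMap,
    compute_occupancy,
    compute_rate_map,
    compute_sac,
    mask_center,
    masked_smooth,
    n_bins_for,
)
from tests.conftest import ARENA, BIN_SIZE, N_BINS, ideal_map


def _rec(t, x, y, spikes=None, arena=(150.0, 150.0)):
    return Recording(t=np.asarray(t, float), x=np.asarray(x, float),
                     y=np.asarray(y, float), spikes=spikes or {}, arena=arena)


def test_stationary_trajectory_occupancy():
    t = np.arange(0.0, 60.0, 0.5)  # 120 samples x 0.5 s
    rec = _rec(t, np.full(t.size, 10.0), np.full(t.size, 10.0))
    occ = compute_occupancy(rec, 3.0)
    assert occ[3, 3] == pytest.approx(60.0)
    assert occ.sum() == pytest.approx(60.0)


def test_four_bin_uniform_sweep():
    # 2 s in each of 4 bins of a 6 cm arena at 3 cm bins, hand-derived dwell
    t = np.arange(0.0, 8.0, 0.5)
    xs = [1.5] * 4 + [4.5] * 4 + [1.5] * 4 + [4.5] * 4
    ys = [1.5] * 8 + [4.5] * 8
    rec = _rec(t, xs, ys, arena=(6.0, 6.0))
    occ = compute_occupancy(rec, 3.0)
    np.testing.assert_allclose(occ, [[2.0, 2.0], [2.0, 2.0]])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_occupancy_conserves_duration(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(10, 300)
    t = np.cumsum(rng.uniform(0.01, 0.2, n))
    x = rng.uniform(0, 150, n)
    y = rng.uniform(0, 150, n)
    occ = compute_occupancy(_rec(t, x, y), 3.0)
    dt = np.diff(t)
    expected = dt.sum() + np.median(dt)  # last sample carries the median interval
    assert occ.sum() == pytest.approx(expected)


def test_bin_size_must_be_positive():
    t = np.arange(0.0, 1.0, 0.1)
    with pytest.raises(ValueError):
        compute_occupancy(_rec(t, t * 0 + 1, t * 0 + 1), 0.0)


def test_rate_definition_and_zero_spike_map():
    t = np.arange(0.0, 60.0, 0.5)
    rec = _rec(t, np.full(t.size, 1.5), np.full(t.size, 1.5),
               spikes={"u": np.array([10.0] * 30), "empty": np.empty(0)},
               arena=(6.0, 6.0))
    rm = compute_rate_map(rec, "u", 3.0, smooth_sigma_bins=0.0)
    assert rm.values[0, 0] == pytest.approx(30 / 60.0)  # 30 spikes over 60 s
    rm0 = compute_rate_map(rec, "empty", 3.0, smooth_sigma_bins=0.0)
    assert rm0.n_spikes == 0
    assert np.all(rm0.values[rm0.visited_mask] == 0.0)
    assert np.all(np.isnan(rm0.values[~rm0.visited_mask]))  # missing, never 0 Hz


def test_masked_smoothing_matches_kernel_sum_oracle():
    rng = np.random.default_rng(5)
    vals = rng.uniform(0, 10, (9, 9))
    mask = np.ones((9, 9), bool)
    sm = masked_smooth(vals, mask, 1.0)
    # independent direct kernel-sum at the center bin (truncation radius 4
    # matches the scipy default of 4 sigma)
    off = np.arange(-4, 5)
    kern = np.exp(-(off[:, None] ** 2 + off[None, :] ** 2) / 2.0)
    expected = np.sum(kern * vals[4 - 4 : 4 + 5, 4 - 4 : 4 + 5]) / kern.sum()
    assert sm[4, 4] == pytest.approx(expected, rel=1e-6)


def test_sac_center_is_one_and_point_symmetric(standard_ideal_map):
    sac = compute_sac(standard_ideal_map)
    ci, cj = sac.center
    assert sac.values[ci, cj] == pytest.approx(1.0)
    v = sac.values
    flipped = v[::-1, ::-1]
    both = np.isfinite(v) & np.isfinite(flipped)
    np.testing.assert_allclose(v[both], flipped[both], atol=1e-7)
    assert sac.shape == (2 * N_BINS - 1, 2 * N_BINS - 1)


def test_sac_of_constant_map_is_degenerate():
    vals = np.full((20, 20), 3.3)
    rm = RateMap(values=vals, occupancy=np.ones_like(vals), bin_size=3.0,
                 visited_mask=np.ones_like(vals, bool))
    sac = compute_sac(rm)
    assert sac.degenerate


def test_sac_inner_peaks_on_grid_lattice(standard_ideal_map):
    """Six inner SAC peaks of an ideal grid sit at radius lambda/bin_size and
    at 60-degree angular steps (lattice-geometry oracle)."""
    from gridvar.gridfit import find_sac_peaks

    sac = mask_center(compute_sac(standard_ideal_map))
    peaks = find_sac_peaks(sac)
    assert len(peaks) >= 6
    ci, cj = sac.center
    d = peaks[:6] - np.array([ci, cj])
    radii = np.hypot(d[:, 0], d[:, 1])
    np.testing.assert_allclose(radii, 85.0 / BIN_SIZE, atol=1.0)
    angles = np.sort(np.mod(np.rad2deg(np.arctan2(d[:, 1], d[:, 0])) - 6.0, 60.0))
    # each peak angle is within ~2 deg of a multiple of 60 from the true axis
    assert np.all(np.minimum(angles, 60.0 - angles) < 2.0)


def test_sac_rotates_with_the_map(standard_ideal_map):
    rm90 = RateMap(
        values=np.rot90(standard_ideal_map.values).copy(),
        occupancy=standard_ideal_map.occupancy,
        bin_size=BIN_SIZE,
        visited_mask=np.ones_like(standard_ideal_map.values, bool),
    )
    sac = compute_sac(standard_ideal_map)
    sac90 = compute_sac(rm90)
    a, b = np.rot90(sac.values), sac90.values
    both = np.isfinite(a) & np.isfinite(b)
    np.testing.assert_allclose(a[both], b[both], atol=1e-7)


def test_mask_center_radius_zero_and_idempotence(standard_ideal_map):
    sac = compute_sac(standard_ideal_map)
    m0 = mask_center(sac, 0)
    ci, cj = sac.center
    assert np.isnan(m0.values[ci, cj])
    changed = np.isnan(m0.values) & np.isfinite(sac.values)
    assert changed.sum() == 1  # only the center bin
    m5 = mask_center(sac, 5)
    m5again = mask_center(m5, 5)
    np.testing.assert_array_equal(np.isnan(m5.values), np.isnan(m5again.values))


@pytest.mark.parametrize("radius", [2, 5, 9])
def test_masked_bin_count_is_lattice_point_count(standard_ideal_map, radius):
    sac = compute_sac(standard_ideal_map)
    masked = mask_center(sac, radius)
    n_masked = int((np.isnan(masked.values) & np.isfinite(sac.values)).sum())
    # brute-force integer lattice points inside the disc
    r = np.arange(-radius, radius + 1)
    expected = int(np.sum(np.hypot(*np.meshgrid(r, r)) <= radius))
    assert n_masked == expected


def test_mask_radius_bound():
    sac = compute_sac(ideal_map())
    with pytest.raises(ValueError):
        mask_center(sac, sac.shape[0] // 2)


def test_recovered_rate_map_converges_to_ideal(long_single_cell_session):
    """A 130-min recording reproduces the ideal map (corr > 0.9), and a
    longer exposure correlates better than a shorter one."""
    from gridvar.gridsim import GridCellParams, ideal_rate_map

    rec, truth = long_single_cell_session
    row = truth.iloc[0]
    params = GridCellParams(row.lambda_cm, row.theta_deg,
                            (row.phase_x_cm, row.phase_y_cm), row.xmax_hz)
    ideal = ideal_rate_map(params, rec.arena, N_BINS)

    def corr_at(duration_s):
        keep = rec.t <= rec.t[0] + duration_s
        sub = Recording(t=rec.t[keep], x=rec.x[keep], y=rec.y[keep],
                        spikes={u: s[s <= rec.t[0] + duration_s] for u, s in rec.spikes.items()},
                        arena=rec.arena)
        rm = compute_rate_map(sub, rec.unit_ids[0], BIN_SIZE, 1.0)
        ok = rm.visited_mask
        return np.corrcoef(rm.values[ok], ideal[ok])[0, 1]

    c_short, c_full = corr_at(15 * 60), corr_at(130 * 60)
    assert c_full > 0.9
    assert c_full > c_short
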