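"""Split-half resampling: splits, shuffles, reliability, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gridvar.gridsim import GridCellParams, GridPopulationSpec, generate_spikes, make_synthetic_session, simulate_trajectory
from gridvar.io_core import AnalysisConfig, Recording, derive_rng
from gridvar.ratemaps import compute_occupancy
from gridvar.variability import (
    VariabilityResult,
    _random_derangement,
    angle_diff_60,
    reliability_filter,
    shuffle_analysis,
    split_halves,
    summarize,
)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(-720, 720), st.floats(-720, 720))
def test_angle_diff_60_properties(a, b):
    d = float(angle_diff_60(a, b))
    assert 0.0 <= d <= 30.0
    assert d == pytest.approx(float(angle_diff_60(b, a)), abs=1e-9)
    assert d == pytest.approx(float(angle_diff_60(a + 60.0, b)), abs=1e-6)


def test_derangement_has_no_fixed_points():
    rng = derive_rng(11)
    for n in (2, 3, 7, 30):
        p = _random_derangement(n, rng)
        assert sorted(p) == list(range(n))
        assert not np.any(p == np.arange(n))


def _trajectory_recording(minutes: float, seed: int = 12) -> Recording:
    t, x, y = simulate_trajectory(minutes * 60.0, rng=derive_rng(seed))
    cell = GridCellParams(85.0, 6.0, (10.0, 20.0), 13.0)
    spikes = {"u0": generate_spikes(t, x, y, cell, (150.0, 150.0), derive_rng(seed, 1))}
    return Recording(t=t, x=x, y=y, spikes=spikes, arena=(150.0, 150.0))


def test_split_bin_counts_for_long_session():
    """A 130-minute session at 30 s bins gives 260 bins, 130 per half."""
    rec = _trajectory_recording(130.0)
    a, b = split_halves(rec, 30.0, derive_rng(13))
    bins_a = set(np.unique(np.floor((a.t - rec.t[0]) / 30.0).astype(int)))
    bins_b = set(np.unique(np.floor((b.t - rec.t[0]) / 30.0).astype(int)))
    assert len(bins_a) == 130 and len(bins_b) == 130
    assert bins_a.isdisjoint(bins_b)
    assert bins_a | bins_b == set(range(260))


def test_split_occupancy_balance_and_partition():
    rec = _trajectory_recording(20.0)
    a, b = split_halves(rec, 30.0, derive_rng(14))
    occ_a = compute_occupancy(a, 3.0).sum()
    occ_b = compute_occupancy(b, 3.0).sum()
    assert abs(occ_a - occ_b) < 30.0  # balanced to within one bin's duration
    # position samples are partitioned: disjoint and jointly complete
    ta, tb = set(a.t.tolist()), set(b.t.tolist())
    assert ta.isdisjoint(tb)
    used = rec.t[(rec.t - rec.t[0]) < 40 * 30.0]
    assert ta | tb == set(used.tolist())
    # spikes follow their bins
    assert a.spikes["u0"].size + b.spikes["u0"].size <= rec.spikes["u0"].size


def test_split_requires_two_bins():
    rec = _trajectory_recording(0.5)
    with pytest.raises(ValueError):
        split_halves(rec, 30.0, derive_rng(15))


def _fake_result(within_l, between_l, n_shuffles=100, n_poor=None):
    n = len(within_l)
    df = pd.DataFrame({
        "unit_id": [f"u{i}" for i in range(n)],
        "mean_within_dtheta": np.asarray(within_l) / 10.0,
        "mean_between_dtheta": np.asarray(between_l) / 10.0,
        "mean_within_dlambda": np.asarray(within_l, float),
        "mean_between_dlambda": np.asarray(between_l, float),
        "n_poor_fits": n_poor if n_poor is not None else np.zeros(n, int),
        "n_within": n_shuffles,
        "n_between": n_shuffles,
        "accepted": True,
    })
    empty = np.zeros((n_shuffles, n))
    return VariabilityResult(
        per_cell=df, n_shuffles=n_shuffles, split_bin_seconds=30.0,
        max_poor_frac=0.05, pairings=np.zeros((n_shuffles, n), int),
        within_theta=empty, within_lambda=empty,
        between_theta=empty, between_lambda=empty,
    )


def test_reliability_threshold_is_strict():
    res = _fake_result([1.0] * 2, [2.0] * 2, n_poor=np.array([4, 5]))
    res.per_cell["accepted"] = (res.per_cell["n_poor_fits"] / 100) < 0.05
    acc = reliability_filter(res)
    assert list(acc["unit_id"]) == ["u0"]  # 4% accepted, 5% rejected


def test_summary_extreme_and_swapped_directions():
    rng = np.random.default_rng(16)
    within = rng.uniform(0.5, 1.5, 8)
    between = within + rng.uniform(0.5, 2.0, 8)  # between > within everywhere
    s = summarize(_fake_result(within, between))
    assert s["pct_between_gt_within_lambda"] == 100.0
    assert s["wilcoxon_p_lambda"] < 0.05
    swapped = summarize(_fake_result(between, within))
    assert swapped["wilcoxon_p_lambda"] >= 0.5
    assert swapped["pct_between_gt_within_lambda"] == 0.0


def test_summary_too_few_cells_gives_nans():
    s = summarize(_fake_result([1.0, 1.0], [2.0, 2.0]))
    assert np.isnan(s["mean_within_dlambda"])
    assert s["n_accepted"] == 2


def test_identical_cells_are_exchangeable():
    """Cells with identical (lambda, theta, phase) should show within ~ between."""
    t, x, y = simulate_trajectory(40 * 60.0, rng=derive_rng(17))
    cell = GridCellParams(85.0, 6.0, (40.0, 80.0), 15.0)
    spikes = {
        f"u{i}": generate_spikes(t, x, y, cell, (150.0, 150.0), derive_rng(17, i + 1))
        for i in range(6)
    }
    rec = Recording(t=t, x=x, y=y, spikes=spikes, arena=(150.0, 150.0))
    cfg = AnalysisConfig(n_shuffles=20, rng_seed=18)
    res = shuffle_analysis(rec, cfg, rng=derive_rng(18))
    s = summarize(res, min_cells=4)
    # no robust heterogeneity: the one-sided test must not fire
    assert s["wilcoxon_p_lambda"] > 0.05
    assert s["wilcoxon_p_theta"] > 0.05


def test_unreliable_noise_cell_is_rejected():
    """A homogeneous-Poisson 'cell' fails the half-session grid fits."""
    t, x, y = simulate_trajectory(40 * 60.0, rng=derive_rng(19))
    arena = (150.0, 150.0)
    good = GridPopulationSpec(n=2, sigma_lambda=0.0, sigma_theta=0.0)
    rng = derive_rng(19, 1)
    spikes = {}
    from gridvar.gridsim import sample_population

    for i, c in enumerate(sample_population(good, rng)):
        spikes[f"grid{i}"] = generate_spikes(t, x, y, c, arena, rng)
    spikes["noise"] = np.sort(rng.uniform(t[0], t[-1], int(5.0 * (t[-1] - t[0]))))
    rec = Recording(t=t, x=x, y=y, spikes=spikes, arena=arena)
    cfg = AnalysisConfig(n_shuffles=10, rng_seed=20)
    res = shuffle_analysis(rec, cfg, rng=derive_rng(20))
    row = res.per_cell.set_index("unit_id").loc["noise"]
    assert not row["accepted"]


def test_results_depend_only_on_data_not_cell_order(short_session):
    rec, _ = short_session
    cfg = AnalysisConfig(n_shuffles=5, rng_seed=21)
    res = shuffle_analysis(rec, cfg, rng=derive_rng(21))
    rev_units = rec.unit_ids[::-1]
    res_rev = shuffle_analysis(rec, cfg, rng=derive_rng(21), units=rev_units)
    a = res.per_cell.set_index("unit_id")["mean_within_dlambda"]
    b = res_rev.per_cell.set_index("unit_id")["mean_within_dlambda"]
    # same splits, same per-cell within values regardless of listing order
    pd.testing.assert_series_equal(a.sort_index(), b.sort_index())
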