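import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enorms.core import (
    CurvePoint,
    EnormsError,
    MeasurementSeries,
    PlateauSeed,
    compute_differences,
    detect_plateau_seed,
    filter_band,
    find_intersections,
    manual_window_stats,
    reference_limits,
    reference_stats,
    run_enorms,
    sort_ascending,
)
from enorms.io import RawColumn


def series(values, resolution=0.1):
    return MeasurementSeries(values=np.asarray(values, dtype=float), resolution=resolution)


def band_seed(low, high):
    """A seed carrying only band limits, for intersection tests."""
    mid = (low + high) / 2
    return PlateauSeed(
        min_diff=0.0, seed_indices=np.array([0, 1]), seed_mean=mid,
        seed_sd=(high - low) / 2, band_low=low, band_high=high,
    )


def brute_force_seed(values, resolution):
    """Independent oracle: scan every consecutive pair, round, collect minima."""
    units = [round(abs(values[i + 1] - values[i]) / resolution) for i in range(len(values) - 1)]
    m = min(units)
    idx: set[int] = set()
    for i, u in enumerate(units):
        if u == m:
            idx |= {i, i + 1}
    return m * resolution, sorted(idx)


# --- sorting and differences -------------------------------------------------

@pytest.mark.parametrize(
    "raw, expected",
    [
        ([3.0, 1.0, 2.0], [1.0, 2.0, 3.0]),
        ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]),
        ([5.0, 5.0, 5.0], [5.0, 5.0, 5.0]),
    ],
)
def test_sort_ascending(raw, expected):
    s = sort_ascending(RawColumn(values=raw))
    assert s.values.tolist() == expected


def test_sort_resolution_inferred_or_overridden():
    raw = RawColumn(values=[1.25, 2.5])
    assert sort_ascending(raw).resolution == pytest.approx(0.01)
    assert sort_ascending(raw, resolution=0.5).resolution == 0.5


@pytest.mark.parametrize(
    "values, expected",
    [
        ([1, 2, 4, 7], [1, 2, 3]),
        ([10.0, 20.0, 20.1, 20.2, 30.0], [10.0, 0.1, 0.1, 9.8]),
        ([5, 5, 5], [0, 0]),
    ],
)
def test_compute_differences(values, expected):
    profile = compute_differences(series(values, resolution=1))
    assert profile.diffs == pytest.approx(expected)
    assert profile.abs_diffs == pytest.approx(np.abs(expected))
    assert profile.diffs.sum() == pytest.approx(values[-1] - values[0])


def test_differences_too_short():
    with pytest.raises(EnormsError, match="too short"):
        compute_differences(series([1.0]))


# --- plateau seed ------------------------------------------------------------

def test_seed_worked_example(worked_series):
    seed = detect_plateau_seed(worked_series)
    assert seed.min_diff == pytest.approx(0.1)
    assert seed.seed_indices.tolist() == [1, 2, 3]
    assert seed.seed_mean == pytest.approx(20.1)
    assert seed.seed_sd == pytest.approx(0.1)
    assert (seed.band_low, seed.band_high) == (pytest.approx(20.0), pytest.approx(20.2))


def test_seed_degenerate_tie_warns():
    with pytest.warns(UserWarning, match="degenerate band"):
        seed = detect_plateau_seed(series([5.0, 5.0, 5.0, 9.0], resolution=1))
    assert seed.min_diff == 0.0
    assert seed.seed_indices.tolist() == [0, 1, 2]
    assert seed.seed_sd == 0.0
    assert seed.band_low == seed.band_high == 5.0


def test_seed_unique_minimum_two_points():
    seed = detect_plateau_seed(series([1.0, 2.0, 4.0, 8.0, 16.0], resolution=1))
    assert seed.seed_indices.tolist() == [0, 1]
    assert seed.seed_mean == pytest.approx(1.5)
    assert seed.seed_sd == pytest.approx(math.sqrt(0.5))


def test_seed_requires_four_points():
    with pytest.raises(EnormsError, match="too short"):
        detect_plateau_seed(series([1.0, 2.0, 3.0]))


# --- band filter and intersections ------------------------------------------

def test_filter_band_worked_example(worked_series):
    seed = detect_plateau_seed(worked_series)
    (lo, hi), filtered = filter_band(worked_series, seed)
    assert (lo, hi) == (1, 3)
    assert filtered.tolist() == [20.0, 20.1, 20.2]


def test_filter_band_saturates_to_whole_series(worked_series):
    (lo, hi), filtered = filter_band(worked_series, band_seed(0.0, 100.0))
    assert (lo, hi) == (0, len(worked_series) - 1)
    assert filtered.tolist() == worked_series.values.tolist()


def test_filter_point_band_retains_ties():
    s = series([5.0, 5.0, 5.0, 9.0], resolution=1)
    (lo, hi), filtered = filter_band(s, band_seed(5.0, 5.0))
    assert (lo, hi) == (0, 2)
    assert filtered.tolist() == [5.0, 5.0, 5.0]


def test_intersection_interpolated_crossing():
    s = series([1.0, 3.0, 5.0], resolution=1)
    first, last = find_intersections(s, band_seed(4.0, 4.0))
    assert (last.x, last.y) == (pytest.approx(1.5), pytest.approx(4.0))


def test_intersections_exact_nodes(worked_series):
    seed = detect_plateau_seed(worked_series)
    first, last = find_intersections(worked_series, seed)
    assert (first.x, first.y) == (1.0, pytest.approx(20.0))
    assert (last.x, last.y) == (3.0, pytest.approx(20.2))


def test_intersection_flat_run_takes_outermost_nodes():
    s = series([1.0, 2.0, 2.0, 2.0, 3.0], resolution=1)
    first, last = find_intersections(s, band_seed(2.0, 2.0))
    assert first.x == 1.0  # leftmost node of the flat run at y = 2
    assert last.x == 3.0   # rightmost


def test_intersection_band_outside_range_clamps(worked_series):
    with pytest.warns(UserWarning, match="clamped"):
        first, last = find_intersections(worked_series, band_seed(-5.0, 99.0))
    assert (first.x, first.y) == (0.0, 10.0)
    assert (last.x, last.y) == (4.0, 30.0)


# --- reference statistics ----------------------------------------------------

def test_reference_stats_worked_example():
    stats = reference_stats([20.0, 20.1, 20.2], CurvePoint(1, 20.0), CurvePoint(3, 20.2))
    assert stats.n == 3
    assert stats.mean == pytest.approx(20.1)
    assert stats.sd == pytest.approx(0.1)
    assert stats.mean_minus_2sd == pytest.approx(19.9)
    assert stats.mean_plus_2sd == pytest.approx(20.3)
    assert (stats.min, stats.max) == (20.0, 20.2)


def test_reference_limits_match_published_convention():
    low, high = reference_limits(44.62, 2.36)
    assert round(low, 2) == 39.90
    assert round(high, 2) == 49.34


def test_reference_stats_singleton_warns():
    with pytest.warns(UserWarning, match="single plateau point"):
        stats = reference_stats([7.0], CurvePoint(0, 7.0), CurvePoint(0, 7.0))
    assert (stats.mean, stats.sd) == (7.0, 0.0)
    assert stats.mean_minus_2sd == stats.mean_plus_2sd == 7.0


# --- full pipeline -----------------------------------------------------------

def test_run_enorms_order_independent(worked_raw, worked_series):
    result = run_enorms(worked_raw)
    seed = detect_plateau_seed(worked_series)
    assert result.stats.n == 3
    assert result.stats.mean == pytest.approx(20.1)
    assert result.seed.seed_indices.tolist() == seed.seed_indices.tolist()
    assert (result.plateau_lo, result.plateau_hi) == (1, 3)


def test_run_enorms_deterministic(worked_raw):
    r1 = run_enorms(worked_raw)
    r2 = run_enorms(worked_raw)
    assert r1.to_dict() == r2.to_dict()


def test_run_enorms_too_short():
    with pytest.raises(EnormsError, match="too short"):
        run_enorms(RawColumn(values=[1.0, 2.0, 3.0]))


# --- manual window -----------------------------------------------------------

def test_manual_window_matches_automated(worked_series):
    manual = manual_window_stats(worked_series, 1, 3)
    auto = run_enorms(RawColumn(values=worked_series.values.tolist()))
    assert manual.to_dict() == auto.stats.to_dict()


def test_manual_window_full_and_one_based(worked_series):
    full = manual_window_stats(worked_series, 0, 4)
    assert full.n == 5
    assert full.mean == pytest.approx(np.mean(worked_series.values))
    one_based = manual_window_stats(worked_series, 2, 4, index_base=1)
    zero_based = manual_window_stats(worked_series, 1, 3)
    assert one_based.to_dict() == zero_based.to_dict()


def test_manual_window_singleton_and_errors(worked_series):
    with pytest.warns(UserWarning, match="single plateau point"):
        stats = manual_window_stats(worked_series, 2, 2)
    assert stats.sd == 0.0
    with pytest.raises(EnormsError, match="invalid window"):
        manual_window_stats(worked_series, 3, 1)
    with pytest.raises(EnormsError, match="invalid window"):
        manual_window_stats(worked_series, 0, 99)


# --- properties --------------------------------------------------------------

sorted_series_strategy = (
    st.lists(
        st.integers(min_value=0, max_value=2000).map(lambda k: k / 10.0),
        min_size=4,
        max_size=50,
    )
    .map(sorted)
    .map(lambda vals: series(vals, resolution=0.1))
)


@settings(max_examples=200, derandomize=True)
@given(sorted_series_strategy)
def test_telescoping_sum(s):
    profile = compute_differences(s)
    assert profile.diffs.sum() == pytest.approx(s.values[-1] - s.values[0], abs=1e-9)


@settings(max_examples=200, derandomize=True)
@given(sorted_series_strategy)
def test_seed_matches_brute_force_oracle(s):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seed = detect_plateau_seed(s)
    oracle_min, oracle_idx = brute_force_seed(s.values.tolist(), s.resolution)
    assert seed.min_diff == pytest.approx(oracle_min)
    assert seed.seed_indices.tolist() == oracle_idx


@settings(max_examples=200, derandomize=True)
@given(sorted_series_strategy)
def test_band_filter_contiguous_and_consistent(s):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seed = detect_plateau_seed(s)
        (lo, hi), filtered = filter_band(s, seed)
        first, last = find_intersections(s, seed)
    eps = s.resolution * 1e-6  # band membership is closed up to float noise
    inside = np.flatnonzero(
        (s.values >= seed.band_low - eps) & (s.values <= seed.band_high + eps)
    )
    assert inside.tolist() == list(range(lo, hi + 1))  # one unbroken run
    assert seed.band_low - eps <= filtered.min() <= filtered.max() <= seed.band_high + eps
    assert seed.band_low <= first.y + eps
    assert last.y <= seed.band_high + eps


@settings(max_examples=100, derandomize=True)
@given(sorted_series_strategy)
def test_manual_window_reproduces_filtered_stats(s):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seed = detect_plateau_seed(s)
        (lo, hi), filtered = filter_band(s, seed)
        auto = reference_stats(filtered, *find_intersections(s, seed))
        manual = manual_window_stats(s, lo, hi)
    assert manual.n == auto.n
    assert manual.mean == pytest.approx(auto.mean)
    assert manual.sd == pytest.approx(auto.sd)
    assert manual.mean_plus_2sd - manual.mean_minus_2sd == pytest.approx(4 * manual.sd)
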