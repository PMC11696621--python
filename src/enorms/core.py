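"""The e-norms plateau algorithm.

Sorting a mixed clinical dataset (normal and abnormal studies pooled,
unlabeled) and plotting it against rank produces an inverted-S curve:
steep tails where abnormal values are sparse, and a near-flat central
plateau where the dominant normal subpopulation clusters.  The method
locates that plateau from the first-order differences of the sorted
data and reports its descriptive statistics as indirect reference
values (mean ± 2 SD of the plateau points).

Pipeline
--------
1. sort ascending                          (``sort_ascending``)
2. consecutive differences                 (``compute_differences``)
3. minimal-difference seed cluster         (``detect_plateau_seed``)
4. keep values inside seed mean ± 1 SD     (``filter_band``)
5. band/curve intersections by linear
   interpolation on the sorted curve       (``find_intersections``)
6. plateau descriptives, mean ± 2 SD       (``reference_stats``)

``run_enorms`` composes the pipeline; ``manual_window_stats`` is the
visual-identification mode where the user supplies the plateau window's
x-coordinates directly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Any, Sequence

import numpy as np

from .io import RawColumn, infer_resolution

__all__ = [
    "MeasurementSeries",
    "DifferenceProfile",
    "PlateauSeed",
    "CurvePoint",
    "ReferenceStats",
    "EnormsResult",
    "sort_ascending",
    "compute_differences",
    "detect_plateau_seed",
    "filter_band",
    "find_intersections",
    "reference_stats",
    "reference_limits",
    "run_enorms",
    "manual_window_stats",
]


class EnormsError(RuntimeError):
    """Fatal algorithmic precondition failure, tagged with the stage name."""


@dataclass
class MeasurementSeries:
    """An ascending-sorted measurement vector with label, units, resolution.

    ``resolution`` is the smallest meaningful value step of the recording
    instrument (e.g. 0.1 m/s for conduction velocity); it drives the tie
    detection in :func:`detect_plateau_seed`.
    """

    values: np.ndarray
    label: str = "value"
    units: str = ""
    resolution: float = 0.1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise EnormsError("series must be one-dimensional")
        if np.any(np.diff(self.values) < 0):
            raise EnormsError("series values must be sorted ascending")
        if self.resolution <= 0:
            raise EnormsError("resolution must be positive")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class DifferenceProfile:
    """First-order differences of a sorted series (the discrete slope)."""

    diffs: np.ndarray
    abs_diffs: np.ndarray


@dataclass
class PlateauSeed:
    """The minimal-difference datapoint cluster and its ±1 SD band.

    ``seed_indices`` contains both endpoints of every consecutive pair
    whose resolution-rounded difference equals the minimum; the band is
    ``seed_mean ± sd_multiplier·seed_sd`` in measurement units.
    """

    min_diff: float
    seed_indices: np.ndarray
    seed_mean: float
    seed_sd: float
    band_low: float
    band_high: float
    sd_multiplier: float = 1.0


@dataclass
class CurvePoint:
    """A point on the piecewise-linear sorted curve; x may be fractional."""

    x: float
    y: float

    def to_dict(self) -> dict[str, float]:
        return {"x": self.x, "y": self.y}


@dataclass
class ReferenceStats:
    """Plateau descriptive statistics: the derived reference values.

    ``mean_minus_2sd`` / ``mean_plus_2sd`` are the reference limits
    (lower/upper bound of the normal range); with a non-default
    reporting multiplier they hold mean ∓ k·SD but keep these names.
    """

    n: int
    mean: float
    sd: float
    mean_minus_2sd: float
    mean_plus_2sd: float
    min: float
    max: float
    first_intersection: CurvePoint
    last_intersection: CurvePoint

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["first_intersection"] = self.first_intersection.to_dict()
        d["last_intersection"] = self.last_intersection.to_dict()
        return d


@dataclass
class EnormsResult:
    """Full outcome of one e-norms run: seed, stats, and the config used."""

    series_label: str
    n_total: int
    seed: PlateauSeed
    stats: ReferenceStats
    plateau_lo: int
    plateau_hi: int
    plateau_values: np.ndarray
    config_echo: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "label": self.series_label,
            "n_total": self.n_total,
            "n_plateau": self.stats.n,
            "min_diff": self.seed.min_diff,
            "seed_indices": [int(i) for i in self.seed.seed_indices],
            "seed_mean": self.seed.seed_mean,
            "seed_sd": self.seed.seed_sd,
            "band_low": self.seed.band_low,
            "band_high": self.seed.band_high,
            "mean": self.stats.mean,
            "sd": self.stats.sd,
            "mean_minus_2sd": self.stats.mean_minus_2sd,
            "mean_plus_2sd": self.stats.mean_plus_2sd,
            "min": self.stats.min,
            "max": self.stats.max,
            "first_intersection": self.stats.first_intersection.to_dict(),
            "last_intersection": self.stats.last_intersection.to_dict(),
            "config": dict(self.config_echo),
        }


def sort_ascending(raw: RawColumn, resolution: float | None = None) -> MeasurementSeries:
    """Sort a raw column into a MeasurementSeries.

    Resolution comes from the argument, then the column's inferred
    resolution, then inference over the values.
    """
    if not raw.values:
        raise EnormsError("sort: empty column")
    res = resolution if resolution is not None else raw.resolution
    if res is None:
        res = infer_resolution(raw.values)
    values = np.sort(np.asarray(raw.values, dtype=float))
    return MeasurementSeries(values=values, label=raw.label, resolution=float(res))


def compute_differences(series: MeasurementSeries) -> DifferenceProfile:
    """Consecutive first-order differences values[i+1] − values[i].

    For sorted input the differences are nonnegative, so ``abs_diffs``
    equals ``diffs``; both are kept because the minimal-change search is
    defined on absolute differences.
    """
    if len(series) < 2:
        raise EnormsError("differences: series too short (need >= 2 values)")
    diffs = np.diff(series.values)
    return DifferenceProfile(diffs=diffs, abs_diffs=np.abs(diffs))


def _round_to_resolution(diffs: np.ndarray, resolution: float) -> np.ndarray:
    """Round differences to integer multiples of the instrument resolution."""
    return np.rint(diffs / resolution).astype(np.int64)


def detect_plateau_seed(
    series: MeasurementSeries,
    profile: DifferenceProfile | None = None,
    sd_multiplier: float = 1.0,
) -> PlateauSeed:
    """Find the minimal-difference cluster and its ±1 SD band.

    Absolute differences are rounded to the series resolution before the
    minimum is taken, so that instrument-level ties (the norm in clinical
    exports) are treated as equal.  Every datapoint touching a minimal
    pair — both endpoints of each pair — enters the seed; the band is the
    sample mean ± ``sd_multiplier`` sample SD of those seed datapoints.
    """
    if len(series) < 4:
        raise EnormsError("plateau: series too short (need >= 4 values)")
    if sd_multiplier <= 0:
        raise EnormsError("plateau: sd_multiplier must be positive")
    if profile is None:
        profile = compute_differences(series)

    units = _round_to_resolution(profile.abs_diffs, series.resolution)
    min_units = int(units.min())
    min_positions = np.flatnonzero(units == min_units)
    seed_indices = np.unique(np.concatenate([min_positions, min_positions + 1]))
    assert len(seed_indices) >= 2  # every minimal pair contributes two points

    seed_values = series.values[seed_indices]
    seed_mean = float(np.mean(seed_values))
    seed_sd = float(np.std(seed_values, ddof=1))
    if seed_sd == 0.0:
        warnings.warn(
            "degenerate band: minimal-difference points are identical; "
            "the ±1 SD band collapses to a point",
            stacklevel=2,
        )
    return PlateauSeed(
        min_diff=min_units * series.resolution,
        seed_indices=seed_indices,
        seed_mean=seed_mean,
        seed_sd=seed_sd,
        band_low=seed_mean - sd_multiplier * seed_sd,
        band_high=seed_mean + sd_multiplier * seed_sd,
        sd_multiplier=sd_multiplier,
    )


def filter_band(
    series: MeasurementSeries, seed: PlateauSeed
) -> tuple[tuple[int, int], np.ndarray]:
    """Retain the values inside the closed band [band_low, band_high].

    Because the series is sorted, the retained indices form one
    contiguous run [lo, hi]; the run and the filtered values are
    returned.
    """
    values = series.values
    eps = _band_eps(series)
    lo = int(np.searchsorted(values, seed.band_low - eps, side="left"))
    hi = int(np.searchsorted(values, seed.band_high + eps, side="right")) - 1
    assert lo <= hi, "closed band cannot exclude its own seed points"
    return (lo, hi), values[lo : hi + 1]


def _band_eps(series: MeasurementSeries) -> float:
    # distinctions far below the instrument resolution are float noise
    return series.resolution * 1e-6


def _first_crossing(values: np.ndarray, level: float, eps: float) -> CurvePoint:
    """Smallest-x intersection of the sorted curve with y = level.

    A datapoint within ``eps`` of the level counts as an exact node
    (leftmost such node for a flat run).
    """
    n = len(values)
    i = int(np.searchsorted(values, level - eps, side="left"))
    if i < n and abs(values[i] - level) <= eps:
        return CurvePoint(x=float(i), y=float(values[i]))
    if i == 0:
        if level < values[0]:
            warnings.warn("band line below data range; clamped to first point", stacklevel=3)
        return CurvePoint(x=0.0, y=float(values[0]))
    if i == n:
        warnings.warn("band line above data range; clamped to last point", stacklevel=3)
        return CurvePoint(x=float(n - 1), y=float(values[-1]))
    x = (i - 1) + (level - values[i - 1]) / (values[i] - values[i - 1])
    return CurvePoint(x=float(x), y=float(level))


def _last_crossing(values: np.ndarray, level: float, eps: float) -> CurvePoint:
    """Largest-x intersection of the sorted curve with y = level.

    A datapoint within ``eps`` of the level counts as an exact node
    (rightmost such node for a flat run).
    """
    n = len(values)
    j = int(np.searchsorted(values, level + eps, side="right")) - 1
    if j >= 0 and abs(values[j] - level) <= eps:
        return CurvePoint(x=float(j), y=float(values[j]))
    if j == n - 1:
        if level > values[-1]:
            warnings.warn("band line above data range; clamped to last point", stacklevel=3)
        return CurvePoint(x=float(n - 1), y=float(values[-1]))
    if j < 0:
        warnings.warn("band line below data range; clamped to first point", stacklevel=3)
        return CurvePoint(x=0.0, y=float(values[0]))
    x = j + (level - values[j]) / (values[j + 1] - values[j])
    return CurvePoint(x=float(x), y=float(level))


def find_intersections(
    series: MeasurementSeries, seed: PlateauSeed
) -> tuple[CurvePoint, CurvePoint]:
    """Band-line intersections with the piecewise-linear sorted curve.

    The sorted data define the curve through (i, values[i]); the first
    intersection is the smallest-x crossing of y = band_low and the last
    is the largest-x crossing of y = band_high.  A band line coinciding
    with a flat run takes the run's outermost node; a line outside the
    data range clamps to the corresponding curve endpoint.
    """
    eps = _band_eps(series)
    first = _first_crossing(series.values, seed.band_low, eps)
    last = _last_crossing(series.values, seed.band_high, eps)
    return first, last


def reference_limits(mean: float, sd: float, multiplier: float = 2.0) -> tuple[float, float]:
    """Reference interval bounds mean ∓ multiplier·SD (default ±2 SD)."""
    return mean - multiplier * sd, mean + multiplier * sd


def reference_stats(
    filtered: Sequence[float] | np.ndarray,
    first: CurvePoint,
    last: CurvePoint,
    ref_multiplier: float = 2.0,
) -> ReferenceStats:
    """Descriptive statistics of the plateau points (sample SD, n−1).

    The mean ± 2 SD bounds are the derived reference limits against
    which an individual measurement is judged.
    """
    filtered = np.asarray(filtered, dtype=float)
    if filtered.size == 0:
        raise EnormsError("stats: no plateau points")
    mean = float(np.mean(filtered))
    if filtered.size == 1:
        warnings.warn("single plateau point: SD reported as 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(np.std(filtered, ddof=1))
    low, high = reference_limits(mean, sd, ref_multiplier)
    return ReferenceStats(
        n=int(filtered.size),
        mean=mean,
        sd=sd,
        mean_minus_2sd=low,
        mean_plus_2sd=high,
        min=float(filtered.min()),
        max=float(filtered.max()),
        first_intersection=first,
        last_intersection=last,
    )


def run_enorms(
    raw: RawColumn,
    resolution: float | None = None,
    sd_multiplier: float = 1.0,
    ref_multiplier: float = 2.0,
) -> EnormsResult:
    """Run the full e-norms pipeline on a raw measurement column.

    Deterministic: identical input and configuration give a bit-identical
    result, independent of the input ordering.
    """
    if len(raw.values) < 4:
        raise EnormsError("run: series too short (need >= 4 values)")
    series = sort_ascending(raw, resolution=resolution)
    profile = compute_differences(series)
    seed = detect_plateau_seed(series, profile, sd_multiplier=sd_multiplier)
    (lo, hi), filtered = filter_band(series, seed)
    first, last = find_intersections(series, seed)
    stats = reference_stats(filtered, first, last, ref_multiplier=ref_multiplier)
    return EnormsResult(
        series_label=raw.label,
        n_total=len(series),
        seed=seed,
        stats=stats,
        plateau_lo=lo,
        plateau_hi=hi,
        plateau_values=filtered,
        config_echo={
            "resolution": series.resolution,
            "sd_multiplier": sd_multiplier,
            "ref_multiplier": ref_multiplier,
        },
    )


def manual_window_stats(
    series: MeasurementSeries,
    left_x: int,
    right_x: int,
    index_base: int = 0,
    ref_multiplier: float = 2.0,
) -> ReferenceStats:
    """Descriptive statistics of a visually chosen plateau window.

    This is the spreadsheet workflow: the user reads the inflection-point
    x-coordinates off the sorted plot and supplies them; the statistics
    of the datapoints between them (inclusive) are returned.  Set
    ``index_base=1`` for spreadsheet-style 1-based coordinates.
    """
    if index_base not in (0, 1):
        raise EnormsError("window: index_base must be 0 or 1")
    left = left_x - index_base
    right = right_x - index_base
    n = len(series)
    if not (0 <= left <= right <= n - 1):
        raise EnormsError(
            f"window: invalid window [{left_x}, {right_x}] for series of length {n} "
            f"(index_base={index_base})"
        )
    window = series.values[left : right + 1]
    first = CurvePoint(x=float(left), y=float(series.values[left]))
    last = CurvePoint(x=float(right), y=float(series.values[right]))
    return reference_stats(window, first, last, ref_multiplier=ref_multiplier)
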