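"""Cell-count utilization surfaces: occupancy time, cumulative and average
activity, and mean temperature per grid cell.

Dwell time follows a symmetric midpoint rule: a fix is credited half of
each adjacent inter-fix interval, with each interval capped at ``max_gap``
so that data dropouts do not inflate occupancy.  Activity indices are
split equally among the fixes falling inside their 30-min interval; a
sample with no in-interval fix is assigned whole to the nearest-in-time
fix (by interval midpoint) within ``max_gap``, otherwise dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .grid import GridSpec, Raster, locate_cells
from .ingest import (
    ActivitySample,
    PositionFix,
    TemperatureSample,
    group_by_animal,
    to_epoch,
)
from .windows import TimeWindow

logger = logging.getLogger(__name__)

DEFAULT_MAX_GAP_S = 21_600.0  # 6 h: longest plausible inactive sampling gap


@dataclass
class AssignmentReport:
    """Bookkeeping for dropped records during cell assignment."""

    n_out_of_bounds: int = 0
    n_dropped_samples: int = 0
    dropped_index_total: float = 0.0
    dropped_seconds: float = 0.0


def _track_arrays(fixes: Sequence[PositionFix]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    times = np.array([to_epoch(f.time) for f in fixes], dtype=float)
    xs = np.array([f.x for f in fixes], dtype=float)
    ys = np.array([f.y for f in fixes], dtype=float)
    if np.isnan(xs).any() or np.isnan(ys).any() or any(f.x is None for f in fixes):
        raise ValueError("fixes must be projected (x/y set) before mapping")
    if np.any(np.diff(times) < 0):
        raise ValueError("fixes must be sorted by time within each animal")
    return times, xs, ys


def dwell_seconds(times: np.ndarray, max_gap: float = DEFAULT_MAX_GAP_S) -> np.ndarray:
    """Symmetric midpoint dwell credit per fix, gaps capped at *max_gap*."""
    n = times.size
    if n < 2:
        return np.zeros(n)
    gaps = np.minimum(np.diff(times), max_gap)
    dwell = np.zeros(n)
    dwell[:-1] += gaps / 2.0
    dwell[1:] += gaps / 2.0
    return dwell


def occupancy_cellcount(
    fixes: Sequence[PositionFix],
    grid: GridSpec,
    window: Optional[TimeWindow] = None,
    max_gap: float = DEFAULT_MAX_GAP_S,
    report: Optional[AssignmentReport] = None,
) -> Raster:
    """Seconds of credited dwell per cell.

    *fixes* may pool several animals; dwell intervals are computed within
    each animal's own track.  A fix contributes if its own timestamp falls
    inside *window*.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    window = window or TimeWindow.full()
    report = report if report is not None else AssignmentReport()
    values = np.zeros((grid.nx, grid.ny))
    for _, track in group_by_animal(fixes).items():
        times, xs, ys = _track_arrays(track)
        dwell = dwell_seconds(times, max_gap)
        keep = window.mask(times)
        ix, iy, ok = locate_cells(grid, xs, ys)
        oob = keep & ~ok
        report.n_out_of_bounds += int(oob.sum())
        report.dropped_seconds += float(dwell[oob].sum())
        sel = keep & ok
        np.add.at(values, (ix[sel], iy[sel]), dwell[sel])
    if report.n_out_of_bounds:
        logger.warning("occupancy: %d out-of-bounds fixes skipped (%.0f s)",
                       report.n_out_of_bounds, report.dropped_seconds)
    return Raster(grid, values, units="seconds")


def _accumulate_activity(
    fixes: Sequence[PositionFix],
    activity: Sequence[ActivitySample],
    grid: GridSpec,
    window: TimeWindow,
    max_gap: float,
    report: AssignmentReport,
) -> tuple[np.ndarray, np.ndarray]:
    """Shared assignment core: per-cell index shares and share weights.

    A fix receiving 1/k of a sample contributes share index/k with weight
    1/k, so ``shares / weights`` is the contribution-weighted mean index.
    """
    shares = np.zeros((grid.nx, grid.ny))
    weights = np.zeros((grid.nx, grid.ny))
    tracks = {}
    for animal, track in group_by_animal(fixes).items():
        times, xs, ys = _track_arrays(track)
        ix, iy, ok = locate_cells(grid, xs, ys)
        tracks[animal] = (times, ix, iy, ok)

    for sample in activity:
        start = to_epoch(sample.interval_start)
        if not window.mask(np.array([start]))[0]:
            continue
        if sample.animal_id not in tracks:
            report.n_dropped_samples += 1
            report.dropped_index_total += sample.index
            continue
        times, ix, iy, ok = tracks[sample.animal_id]
        i0 = np.searchsorted(times, start, side="left")
        i1 = np.searchsorted(times, start + sample.interval_length, side="left")
        if i1 > i0:
            idxs = np.arange(i0, i1)
        else:
            mid = start + sample.interval_length / 2.0
            j = np.searchsorted(times, mid)
            cands = [k for k in (j - 1, j) if 0 <= k < times.size]
            if not cands:
                idxs = np.array([], dtype=int)
            else:
                best = min(cands, key=lambda k: abs(times[k] - mid))
                idxs = (np.array([best]) if abs(times[best] - mid) <= max_gap
                        else np.array([], dtype=int))
        if idxs.size == 0:
            report.n_dropped_samples += 1
            report.dropped_index_total += sample.index
            continue
        k = idxs.size
        in_b = ok[idxs]
        report.n_out_of_bounds += int((~in_b).sum())
        report.dropped_index_total += float((~in_b).sum()) * sample.index / k
        use = idxs[in_b]
        np.add.at(shares, (ix[use], iy[use]), sample.index / k)
        np.add.at(weights, (ix[use], iy[use]), 1.0 / k)
        if not in_b.all() and in_b.sum() == 0:
            report.n_dropped_samples += 1
    return shares, weights


def cumulative_activity_cellcount(
    fixes: Sequence[PositionFix],
    activity: Sequence[ActivitySample],
    grid: GridSpec,
    window: Optional[TimeWindow] = None,
    max_gap: float = DEFAULT_MAX_GAP_S,
    report: Optional[AssignmentReport] = None,
) -> Raster:
    """Total activity-index counts assigned to each cell."""
    window = window or TimeWindow.full()
    report = report if report is not None else AssignmentReport()
    shares, _ = _accumulate_activity(fixes, activity, grid, window, max_gap, report)
    if report.n_dropped_samples:
        logger.warning("cumulative activity: %d samples dropped (index total %.0f)",
                       report.n_dropped_samples, report.dropped_index_total)
    return Raster(grid, shares, units="activity counts")


def average_activity_cellcount(
    fixes: Sequence[PositionFix],
    activity: Sequence[ActivitySample],
    grid: GridSpec,
    window: Optional[TimeWindow] = None,
    max_gap: float = DEFAULT_MAX_GAP_S,
    report: Optional[AssignmentReport] = None,
) -> Raster:
    """Contribution-weighted mean activity index per cell (NaN = no data)."""
    window = window or TimeWindow.full()
    report = report if report is not None else AssignmentReport()
    shares, weights = _accumulate_activity(fixes, activity, grid, window, max_gap, report)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(weights > 0, shares / np.where(weights > 0, weights, 1.0), np.nan)
    return Raster(grid, mean, units="activity index")


def mean_temperature_cellcount(
    fixes: Sequence[PositionFix],
    temps: Sequence[TemperatureSample],
    grid: GridSpec,
    window: Optional[TimeWindow] = None,
    max_gap: float = DEFAULT_MAX_GAP_S,
    report: Optional[AssignmentReport] = None,
) -> tuple[Raster, Raster]:
    """Mean collar temperature per cell plus the per-cell sample count.

    Each temperature sample is located at the nearest-in-time fix of the
    same animal (within *max_gap*); cells with no samples are NaN.
    """
    window = window or TimeWindow.full()
    report = report if report is not None else AssignmentReport()
    total = np.zeros((grid.nx, grid.ny))
    count = np.zeros((grid.nx, grid.ny))
    tracks = {}
    for animal, track in group_by_animal(fixes).items():
        times, xs, ys = _track_arrays(track)
        ix, iy, ok = locate_cells(grid, xs, ys)
        tracks[animal] = (times, ix, iy, ok)

    for sample in temps:
        t = to_epoch(sample.time)
        if not window.mask(np.array([t]))[0] or sample.animal_id not in tracks:
            report.n_dropped_samples += sample.animal_id not in tracks
            continue
        times, ix, iy, ok = tracks[sample.animal_id]
        j = np.searchsorted(times, t)
        cands = [k for k in (j - 1, j) if 0 <= k < times.size]
        if not cands:
            report.n_dropped_samples += 1
            continue
        best = min(cands, key=lambda k: abs(times[k] - t))
        if abs(times[best] - t) > max_gap or not ok[best]:
            report.n_dropped_samples += 1
            continue
        total[ix[best], iy[best]] += sample.temp_c
        count[ix[best], iy[best]] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.where(count > 0, count, 1.0), np.nan)
    return Raster(grid, mean, units="degrees C"), Raster(grid, count, units="samples")
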