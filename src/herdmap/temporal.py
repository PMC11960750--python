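"""Activity-index validation against grazing observations, intensity
thresholding, bouts, diurnal/fortnight profiles and temperature series."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import (
    GRAZING,
    NON_GRAZING,
    ActivitySample,
    ObservationMinute,
    TemperatureSample,
    group_by_animal,
    to_epoch,
)
from .windows import TimeWindow

logger = logging.getLogger(__name__)

DEFAULT_INTENSITY_THRESHOLD = 2500


@dataclass
class GrazingPeriod:
    """One 30-min activity interval with matched observation coverage."""

    animal_id: str
    period_start: object
    proportion_grazing: float
    activity_index: int
    minutes_observed: int


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass
class Bout:
    animal_id: str
    label: str
    start_minute: object
    duration_min: int


def grazing_proportions(
    obs: Sequence[ObservationMinute],
    activity: Sequence[ActivitySample],
    min_coverage: float = 1.0,
) -> list[GrazingPeriod]:
    """Join observation minutes onto activity intervals.

    A period is emitted when the fraction of its minutes that were
    observed reaches *min_coverage* (default: fully observed); the
    grazing proportion is computed over the observed minutes only.
    """
    obs_by_animal: dict[str, dict[float, str]] = {}
    for o in obs:
        obs_by_animal.setdefault(o.animal_id, {})[to_epoch(o.minute)] = o.label

    periods: list[GrazingPeriod] = []
    n_excluded = 0
    for s in sorted(activity, key=lambda a: (a.animal_id, to_epoch(a.interval_start))):
        minutes = obs_by_animal.get(s.animal_id)
        if not minutes:
            continue
        start = to_epoch(s.interval_start)
        n_slots = int(s.interval_length // 60)
        observed = grazing = 0
        for k in range(n_slots):
            label = minutes.get(start + 60.0 * k)
            if label is not None:
                observed += 1
                grazing += label == GRAZING
        if observed == 0:
            continue
        if observed / n_slots < min_coverage:
            n_excluded += 1
            continue
        periods.append(
            GrazingPeriod(
                animal_id=s.animal_id,
                period_start=s.interval_start,
                proportion_grazing=grazing / observed,
                activity_index=s.index,
                minutes_observed=observed,
            )
        )
    if n_excluded:
        logger.info("grazing_proportions: %d partially observed periods excluded",
                    n_excluded)
    return periods


def fit_activity_grazing_line(periods: Sequence[GrazingPeriod]) -> LinearFit:
    """OLS of activity index on observed grazing proportion."""
    if len(periods) < 3:
        raise ValueError("at least 3 periods are required")
    x = np.array([p.proportion_grazing for p in periods], dtype=float)
    y = np.array([p.activity_index for p in periods], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("grazing proportion is constant; cannot fit a line")
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        p_value=float(res.pvalue),
        n=len(periods),
    )


def threshold_from_fit(fit: LinearFit, proportion: float) -> float:
    """Fitted activity index at a given grazing proportion."""
    if fit.slope == 0:
        raise ValueError("zero slope: threshold is undefined")
    return fit.intercept + fit.slope * proportion


def midpoint_threshold(max_nongrazing_index: float, min_grazing_index: float) -> int:
    """Integer midpoint of the two class extremes, half rounded away from zero."""
    if max_nongrazing_index < 0 or min_grazing_index < 0:
        raise ValueError("activity indices are non-negative")
    m = (max_nongrazing_index + min_grazing_index) / 2.0
    return int(math.floor(m + 0.5)) if m >= 0 else int(math.ceil(m - 0.5))


def classify_intensity(
    activity: Sequence[ActivitySample],
    threshold: int = DEFAULT_INTENSITY_THRESHOLD,
    tz_offset_hours: float = 0.0,
) -> tuple[list[str], pd.DataFrame]:
    """Label samples low/high intensity and count labels per animal-day.

    ``high`` iff ``index >= threshold`` so the two labels partition all
    values.  Day boundaries honour the configured timezone offset.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    labels = ["high" if s.index >= threshold else "low" for s in activity]
    if not activity:
        return labels, pd.DataFrame(columns=["animal_id", "date", "low", "high"])
    offset = timedelta(hours=tz_offset_hours)
    rows = [
        {"animal_id": s.animal_id,
         "date": (pd.Timestamp(to_epoch(s.interval_start), unit="s") + offset).date(),
         "label": lab}
        for s, lab in zip(activity, labels)
    ]
    df = pd.DataFrame(rows)
    daily = (
        df.groupby(["animal_id", "date", "label"]).size().unstack(fill_value=0)
        .reindex(columns=["low", "high"], fill_value=0)
        .reset_index()
    )
    daily.columns.name = None
    return labels, daily


def hourly_profile(
    activity: Sequence[ActivitySample],
    group: str = "combined",
    window: Optional[TimeWindow] = None,
    tz_offset_hours: float = 0.0,
) -> pd.DataFrame:
    """Mean activity index per local hour of day.

    Returns a tidy frame with columns ``animal_id, hour, mean_index, n``;
    hours with no samples keep ``n = 0`` and NaN mean.  ``group`` is
    ``combined`` (pool all animals under id "combined") or ``per_animal``.
    """
    if group not in {"combined", "per_animal"}:
        raise ValueError("group must be 'combined' or 'per_animal'")
    window = window or TimeWindow.full()
    epochs = np.array([to_epoch(s.interval_start) for s in activity], dtype=float)
    keep = window.mask(epochs) if epochs.size else np.zeros(0, bool)
    hours = TimeWindow(tz_offset_hours=tz_offset_hours).local_hours(epochs)
    rows = []
    for s, h, k in zip(activity, hours, keep):
        if k:
            aid = "combined" if group == "combined" else s.animal_id
            rows.append({"animal_id": aid, "hour": int(h), "index": s.index})
    df = pd.DataFrame(rows, columns=["animal_id", "hour", "index"])
    animals = ["combined"] if group == "combined" else sorted(df["animal_id"].unique())
    full = pd.MultiIndex.from_product([animals, range(24)], names=["animal_id", "hour"])
    agg = (
        df.groupby(["animal_id", "hour"])["index"].agg(["mean", "size"])
        .reindex(full)
    )
    agg["size"] = agg["size"].fillna(0).astype(int)
    return agg.rename(columns={"mean": "mean_index", "size": "n"}).reset_index()


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value uses the usual t approximation with n - 2 degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series lengths differ")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return rho, float(p)


def extract_bouts(
    obs: Sequence[ObservationMinute],
) -> tuple[list[Bout], dict[str, float]]:
    """Maximal same-label runs per animal; gaps between observation
    sessions terminate a bout.  Also returns mean duration (s) per label."""
    bouts: list[Bout] = []
    for animal, minutes in group_by_animal(obs).items():
        minutes = sorted(minutes, key=lambda o: to_epoch(o.minute))
        run_start = None
        run_label = None
        run_len = 0
        prev_t = None
        for o in minutes:
            t = to_epoch(o.minute)
            contiguous = prev_t is not None and (t - prev_t) == 60.0
            if run_label == o.label and contiguous:
                run_len += 1
            else:
                if run_label is not None:
                    bouts.append(Bout(animal, run_label, run_start, run_len))
                run_start, run_label, run_len = o.minute, o.label, 1
            prev_t = t
        if run_label is not None:
            bouts.append(Bout(animal, run_label, run_start, run_len))
    means = {}
    for label in (GRAZING, NON_GRAZING):
        durs = [b.duration_min for b in bouts if b.label == label]
        if durs:
            means[label] = 60.0 * float(np.mean(durs))
    return bouts, means


@dataclass
class TemperatureComparison:
    rho: float
    p_value: float
    hourly: pd.DataFrame          # columns: hour_start, sensor_c, station_c
    mean_offset_c: float          # mean sensor minus station


def series_compare_temperature(
    sensor: Sequence[TemperatureSample],
    station: pd.DataFrame,
) -> TemperatureComparison:
    """Compare collar temperatures to an hourly weather-station series.

    *station* needs columns ``time`` (hourly, ISO-8601 or datetime) and
    ``temp_c``.  Sensor samples are averaged per clock hour, joined to
    station hours, and rank-correlated.
    """
    if not len(sensor):
        raise ValueError("no sensor samples")
    sens = pd.DataFrame({
        "hour_start": [pd.Timestamp(to_epoch(s.time), unit="s").floor("h")
                       for s in sensor],
        "temp_c": [s.temp_c for s in sensor],
    })
    sens = sens.groupby("hour_start", as_index=False)["temp_c"].mean()
    stat = station.copy()
    stat["hour_start"] = pd.to_datetime(stat["time"], utc=True).dt.tz_localize(None).dt.floor("h")
    stat = stat.groupby("hour_start", as_index=False)["temp_c"].mean()
    joined = sens.merge(stat, on="hour_start", suffixes=("_sensor", "_station"))
    if joined.empty:
        raise ValueError("sensor and station series do not overlap in time")
    rho, p = spearman_rho(joined["temp_c_sensor"], joined["temp_c_station"])
    hourly = joined.rename(
        columns={"temp_c_sensor": "sensor_c", "temp_c_station": "station_c"}
    )
    offset = float((hourly["sensor_c"] - hourly["station_c"]).mean())
    return TemperatureComparison(rho=rho, p_value=p, hourly=hourly,
                                 mean_offset_c=offset)
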