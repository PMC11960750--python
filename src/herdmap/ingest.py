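"""Reading, validating and projecting collar telemetry and observation data.

Collar exports are expected in a canonical delimited layout with columns
``animal_id, time, record_type, lat, lon, activity_index, temp_c`` where
``record_type`` is one of ``fix``, ``activity`` or ``temperature`` and
unused fields are left empty.  A column-name mapping can adapt other
layouts.  All timestamps are ISO-8601 and held internally as UTC.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
import math
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0

GRAZING = "grazing"
NON_GRAZING = "non_grazing"
_LABELS = {GRAZING, NON_GRAZING}

CANONICAL_COLLAR_COLUMNS = (
    "animal_id",
    "time",
    "record_type",
    "lat",
    "lon",
    "activity_index",
    "temp_c",
)


class SchemaError(ValueError):
    """A declared input column is missing or the layout cannot be used."""


class ValidationError(ValueError):
    """A row violates a data-model invariant."""


@dataclass(frozen=True)
class ReferencePoint:
    """Projection origin in WGS84 degrees."""

    lat0: float
    lon0: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat0 <= 90.0 and -180.0 <= self.lon0 <= 180.0):
            raise ValidationError(f"invalid reference point ({self.lat0}, {self.lon0})")


@dataclass
class PositionFix:
    """One timestamped GPS location of one animal.

    ``x``/``y`` are metric offsets east/north of a :class:`ReferencePoint`
    and are ``None`` until :func:`project_coordinates` is applied.
    """

    animal_id: str
    time: datetime
    lat: float
    lon: float
    x: Optional[float] = None
    y: Optional[float] = None


@dataclass
class ActivitySample:
    """One cumulative activity-index count over a 30-min interval."""

    animal_id: str
    interval_start: datetime
    index: int
    interval_length: float = 1800.0


@dataclass
class TemperatureSample:
    """One instantaneous collar temperature reading."""

    animal_id: str
    time: datetime
    temp_c: float


@dataclass
class ObservationMinute:
    """One minute of direct behavioural observation."""

    animal_id: str
    minute: datetime
    label: str
    observer_id: str = ""


@dataclass
class IngestReport:
    n_fixes: int = 0
    n_activity: int = 0
    n_temperature: int = 0
    n_dropped_duplicates: int = 0


@dataclass
class CollarData:
    """Parsed collar streams plus an ingest report.

    Iterable as ``fixes, activity, temperature = data`` for convenience.
    """

    fixes: list
    activity: list
    temperature: list
    report: IngestReport = field(default_factory=IngestReport)

    def __iter__(self) -> Iterator[list]:
        return iter((self.fixes, self.activity, self.temperature))


def to_epoch(t: datetime) -> float:
    """Seconds since the Unix epoch; naive datetimes are taken as UTC."""
    if t.tzinfo is None:
        t = t.replace(tzinfo=timezone.utc)
    return t.timestamp()


def from_epoch(s: float) -> datetime:
    return datetime.fromtimestamp(s, tz=timezone.utc)


def _parse_times(raw: pd.Series, path: str) -> pd.Series:
    parsed = pd.to_datetime(raw, utc=True, errors="coerce", format="mixed")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 to 1-based
        raise ValidationError(
            f"{path}: unparseable timestamp {raw[bad.idxmax()]!r} at line {line}"
        )
    return parsed


def _read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)


def read_collar_records(
    path: str,
    schema: Optional[Mapping[str, str]] = None,
) -> CollarData:
    """Read collar telemetry from a delimited text file.

    Parameters
    ----------
    path:
        CSV/TSV file in the canonical layout (or mapped via *schema*).
    schema:
        Optional mapping from canonical column names to the file's column
        names, e.g. ``{"animal_id": "serial_number"}``.

    Returns
    -------
    CollarData
        Position fixes, activity samples and temperature samples, each
        sorted by ``(animal_id, time)`` with exact duplicate timestamps per
        animal deduplicated (first occurrence kept).
    """
    df = _read_table(path)
    mapping = {c: c for c in CANONICAL_COLLAR_COLUMNS}
    if schema:
        mapping.update(schema)
    for canonical, actual in mapping.items():
        if actual not in df.columns:
            raise SchemaError(f"{path}: missing column {actual!r} (for {canonical!r})")
    df = df.rename(columns={v: k for k, v in mapping.items()})
    df["time"] = _parse_times(df["time"], path)
    df = df.sort_values(["animal_id", "time"], kind="stable").reset_index(drop=True)

    report = IngestReport()
    fixes: list[PositionFix] = []
    activity: list[ActivitySample] = []
    temps: list[TemperatureSample] = []
    seen: dict[tuple, set] = {"fix": set(), "activity": set(), "temperature": set()}

    for row in df.itertuples(index=False):
        kind = row.record_type
        if kind not in seen:
            raise ValidationError(f"{path}: unknown record_type {kind!r}")
        key = (row.animal_id, row.time)
        if key in seen[kind]:
            report.n_dropped_duplicates += 1
            continue
        seen[kind].add(key)
        t = row.time.to_pydatetime()
        if kind == "fix":
            lat, lon = float(row.lat), float(row.lon)
            if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
                raise ValidationError(f"{path}: coordinates out of range ({lat}, {lon})")
            fixes.append(PositionFix(row.animal_id, t, lat, lon))
        elif kind == "activity":
            idx = int(float(row.activity_index))
            if idx < 0:
                raise ValidationError(f"{path}: negative activity index {idx}")
            activity.append(ActivitySample(row.animal_id, t, idx))
        else:
            temps.append(TemperatureSample(row.animal_id, t, float(row.temp_c)))

    report.n_fixes = len(fixes)
    report.n_activity = len(activity)
    report.n_temperature = len(temps)
    if report.n_dropped_duplicates:
        logger.warning(
            "%s: dropped %d duplicate-timestamp rows", path, report.n_dropped_duplicates
        )
    logger.info(
        "%s: %d fixes, %d activity samples, %d temperature samples",
        path, report.n_fixes, report.n_activity, report.n_temperature,
    )
    return CollarData(fixes, activity, temps, report)


def write_collar_records(
    path: str,
    fixes: Sequence[PositionFix] = (),
    activity: Sequence[ActivitySample] = (),
    temperature: Sequence[TemperatureSample] = (),
) -> None:
    """Write streams back to the canonical collar CSV layout."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CANONICAL_COLLAR_COLUMNS)
        for f in fixes:
            w.writerow([f.animal_id, _iso(f.time), "fix",
                        repr(float(f.lat)), repr(float(f.lon)), "", ""])
        for a in activity:
            w.writerow([a.animal_id, _iso(a.interval_start), "activity",
                        "", "", a.index, ""])
        for t in temperature:
            w.writerow([t.animal_id, _iso(t.time), "temperature",
                        "", "", "", repr(float(t.temp_c))])


def _iso(t: datetime) -> str:
    if t.tzinfo is None:
        t = t.replace(tzinfo=timezone.utc)
    return t.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%S%z")


def project_coordinates(
    fixes: Iterable[PositionFix], ref: ReferencePoint
) -> list[PositionFix]:
    """Populate metric ``x``/``y`` via a local equirectangular projection.

    x = R cos(lat0) (lon - lon0), y = R (lat - lat0), angles in radians,
    R = 6,371,000 m.  Exact inverse is :func:`unproject_coordinates`.
    """
    if ref is None:
        raise ValueError("reference point is required for projection")
    coslat = math.cos(math.radians(ref.lat0))
    out = []
    warned = False
    for f in fixes:
        if abs(f.lat - ref.lat0) > 1.0 and not warned:
            warnings.warn(
                "fix more than 1 degree of latitude from the reference point; "
                "equirectangular distortion may be significant",
                stacklevel=2,
            )
            warned = True
        x = EARTH_RADIUS_M * coslat * math.radians(f.lon - ref.lon0)
        y = EARTH_RADIUS_M * math.radians(f.lat - ref.lat0)
        out.append(dataclasses.replace(f, x=x, y=y))
    return out


def unproject_coordinates(x: float, y: float, ref: ReferencePoint) -> tuple[float, float]:
    """Inverse of :func:`project_coordinates`; returns ``(lat, lon)``."""
    lat = ref.lat0 + math.degrees(y / EARTH_RADIUS_M)
    lon = ref.lon0 + math.degrees(x / (EARTH_RADIUS_M * math.cos(math.radians(ref.lat0))))
    return lat, lon


def normalize_label(raw: str) -> str:
    label = str(raw).strip().lower().replace("-", "_").replace(" ", "_")
    if label == "nongrazing":
        label = NON_GRAZING
    if label not in _LABELS:
        raise ValidationError(f"unknown observation label {raw!r}")
    return label


def read_observation_minutes(path: str) -> list[ObservationMinute]:
    """Read per-minute behavioural labels.

    Expects columns ``animal_id, minute, label, observer_id`` (observer_id
    optional).  Labels are normalized case-insensitively to ``grazing`` /
    ``non_grazing``; a minute labelled both ways is an error.
    """
    df = _read_table(path)
    for col in ("animal_id", "minute", "label"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    df["minute"] = _parse_times(df["minute"], path).dt.floor("min")
    if "observer_id" not in df.columns:
        df["observer_id"] = ""
    df["observer_id"] = df["observer_id"].fillna("")
    df["label"] = df["label"].map(normalize_label)
    df = df.sort_values(["animal_id", "minute"], kind="stable")

    out: list[ObservationMinute] = []
    last: dict[tuple, str] = {}
    for row in df.itertuples(index=False):
        key = (row.animal_id, row.minute)
        if key in last:
            if last[key] != row.label:
                raise ValidationError(
                    f"{path}: conflicting labels for {row.animal_id} at {row.minute}"
                )
            continue
        last[key] = row.label
        out.append(
            ObservationMinute(row.animal_id, row.minute.to_pydatetime(),
                              row.label, str(row.observer_id))
        )
    return out


def write_observation_minutes(path: str, obs: Sequence[ObservationMinute]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["animal_id", "minute", "label", "observer_id"])
        for o in obs:
            w.writerow([o.animal_id, _iso(o.minute), o.label, o.observer_id])


def group_by_animal(records: Iterable, key: str = "animal_id") -> dict[str, list]:
    """Stable grouping of dataclass records by animal id."""
    out: dict[str, list] = {}
    for r in records:
        out.setdefault(getattr(r, key), []).append(r)
    return out
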