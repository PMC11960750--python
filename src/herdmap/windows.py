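"""Temporal filters used by every mapping and profile operation.

Time-of-day bins follow the study convention: night 00:00:00-05:59:59,
morning 06:00:00-11:59:59, afternoon 12:00:00-17:59:59, evening
18:00:00-23:59:59.  Fortnights are consecutive 14-day blocks counted from
an anchor time (normally the first record); records beyond the last
declared fortnight are folded into it by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Optional

import numpy as np

from .ingest import to_epoch

DAY_S = 86_400.0
FORTNIGHT_S = 14 * DAY_S

TIME_OF_DAY_HOURS = {
    "night": (0, 6),
    "morning": (6, 12),
    "afternoon": (12, 18),
    "evening": (18, 24),
}


@dataclass(frozen=True)
class TimeWindow:
    """Predicate over timestamps, vectorized over epoch-second arrays."""

    kind: str = "full"
    hour: Optional[int] = None
    tod: Optional[str] = None
    fortnight_index: Optional[int] = None  # 1-based
    anchor_epoch: Optional[float] = None
    n_fortnights: int = 4
    clamp_last: bool = True
    start_epoch: Optional[float] = None
    end_epoch: Optional[float] = None
    tz_offset_hours: float = 0.0

    @classmethod
    def full(cls) -> "TimeWindow":
        return cls("full")

    @classmethod
    def hour_of_day(cls, hour: int, tz_offset_hours: float = 0.0) -> "TimeWindow":
        if not 0 <= hour <= 23:
            raise ValueError("hour must be in 0..23")
        return cls("hour_of_day", hour=hour, tz_offset_hours=tz_offset_hours)

    @classmethod
    def time_of_day(cls, name: str, tz_offset_hours: float = 0.0) -> "TimeWindow":
        if name not in TIME_OF_DAY_HOURS:
            raise ValueError(f"unknown time-of-day bin {name!r}")
        return cls("time_of_day", tod=name, tz_offset_hours=tz_offset_hours)

    @classmethod
    def fortnight(
        cls,
        index: int,
        anchor: datetime,
        n_fortnights: int = 4,
        clamp_last: bool = True,
    ) -> "TimeWindow":
        if index < 1:
            raise ValueError("fortnight index is 1-based")
        return cls(
            "fortnight",
            fortnight_index=index,
            anchor_epoch=to_epoch(anchor),
            n_fortnights=n_fortnights,
            clamp_last=clamp_last,
        )

    @classmethod
    def custom(cls, start: datetime, end: datetime) -> "TimeWindow":
        s, e = to_epoch(start), to_epoch(end)
        if e <= s:
            raise ValueError("window end must be after start")
        return cls("custom", start_epoch=s, end_epoch=e)

    def local_hours(self, epochs: np.ndarray) -> np.ndarray:
        """Local hour of day (0..23) for each epoch second."""
        t = np.asarray(epochs, dtype=float) + self.tz_offset_hours * 3600.0
        return np.floor((t % DAY_S) / 3600.0).astype(int)

    def mask(self, epochs: np.ndarray) -> np.ndarray:
        """Boolean inclusion mask over an array of epoch seconds."""
        t = np.asarray(epochs, dtype=float)
        if self.kind == "full":
            return np.ones(t.shape, dtype=bool)
        if self.kind == "hour_of_day":
            return self.local_hours(t) == self.hour
        if self.kind == "time_of_day":
            lo, hi = TIME_OF_DAY_HOURS[self.tod]
            h = self.local_hours(t)
            return (h >= lo) & (h < hi)
        if self.kind == "fortnight":
            block = np.floor((t - self.anchor_epoch) / FORTNIGHT_S).astype(int)
            k = self.fortnight_index - 1
            if self.clamp_last and self.fortnight_index == self.n_fortnights:
                return block >= k
            return block == k
        if self.kind == "custom":
            return (t >= self.start_epoch) & (t < self.end_epoch)
        raise ValueError(f"unknown window kind {self.kind!r}")

    def contains(self, when: datetime) -> bool:
        return bool(self.mask(np.array([to_epoch(when)]))[0])


def time_of_day_windows(tz_offset_hours: float = 0.0) -> dict[str, TimeWindow]:
    """The four canonical diurnal windows, partitioning every timestamp."""
    return {
        name: TimeWindow.time_of_day(name, tz_offset_hours)
        for name in TIME_OF_DAY_HOURS
    }


def parse_window(spec: str, anchor: Optional[datetime] = None,
                 tz_offset_hours: float = 0.0) -> TimeWindow:
    """Parse CLI window syntax: ``full``, ``tod:<name>``, ``hour:<h>``,
    ``fortnight:<k>`` (needs *anchor*)."""
    if spec == "full":
        return TimeWindow.full()
    kind, _, arg = spec.partition(":")
    if kind == "tod":
        return TimeWindow.time_of_day(arg, tz_offset_hours)
    if kind == "hour":
        return TimeWindow.hour_of_day(int(arg), tz_offset_hours)
    if kind == "fortnight":
        if anchor is None:
            raise ValueError("fortnight windows need an anchor time")
        return TimeWindow.fortnight(int(arg), anchor)
    raise ValueError(f"unknown window spec {spec!r}")
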