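"""Synthetic collar telemetry with known ground truth.

Generates a herd of animals moving through a bounded field under a
semi-Markov behavioural process (resting / grazing / traveling) with
hour-of-day modulated dwell times, and emits the three collar streams
(GPS fixes on the active/inactive schedule, 30-min activity counts,
30-min temperature readings) plus per-minute true positions and states
for oracle tests.  Everything is driven by a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Point, Polygon

from .grid import GridSpec, Raster, locate_cells
from .ingest import (
    ActivitySample,
    ObservationMinute,
    PositionFix,
    ReferencePoint,
    TemperatureSample,
    from_epoch,
    to_epoch,
    unproject_coordinates,
)
from .windows import TimeWindow

RESTING, GRAZING_STATE, TRAVELING = 0, 1, 2
STATE_NAMES = ("resting", "grazing", "traveling")

#: projection origin used to synthesize lat/lon for emitted fixes
DEFAULT_REFERENCE = ReferencePoint(51.902883, 0.910765)


@dataclass(frozen=True)
class StateConfig:
    step_sd_m: float            # per-minute movement scale
    mean_dwell_min: float       # baseline mean dwell before hourly modulation
    activity_mean: float        # mean 30-min activity count when fully in state


@dataclass
class SimConfig:
    n_animals: int = 3
    start: datetime = field(
        default_factory=lambda: datetime(2023, 9, 29, tzinfo=timezone.utc)
    )
    duration_days: int = 58
    # projected metres; default is a 350 x 300 m rectangle
    field_polygon: tuple = ((0.0, 0.0), (350.0, 0.0), (350.0, 300.0), (0.0, 300.0))
    attractors: tuple = ((25.0, 275.0), (300.0, 60.0), (70.0, 150.0))
    resting: StateConfig = field(default_factory=lambda: StateConfig(0.3, 70.0, 600.0))
    grazing: StateConfig = field(default_factory=lambda: StateConfig(2.5, 40.0, 4200.0))
    traveling: StateConfig = field(default_factory=lambda: StateConfig(16.0, 6.0, 2800.0))
    activity_dispersion: float = 12.0   # gamma shape of the count mixture
    fix_interval_active_min: int = 15
    resting_gap_min: tuple = (60, 120)
    temp_base_c: float = 14.0
    temp_daily_amp_c: float = 4.0
    temp_peak_hour: float = 14.0
    temp_trend_c_per_day: float = -0.12
    temp_gradient_c_per_m: float = 0.004
    temp_noise_sd_c: float = 0.7
    location_error_sd_m: float = 5.0
    reference: ReferencePoint = field(default_factory=lambda: DEFAULT_REFERENCE)
    seed: int = 42

    def state_config(self, state: int) -> StateConfig:
        return (self.resting, self.grazing, self.traveling)[state]


@dataclass
class AnimalTruth:
    """Per-minute ground truth for one animal."""

    animal_id: str
    minute_epochs: np.ndarray   # seconds since epoch, 60-s spacing
    x: np.ndarray
    y: np.ndarray
    state: np.ndarray           # int8 state codes


@dataclass
class SyntheticDataset:
    config: SimConfig
    fixes: list
    activity: list
    temperature: list
    truth: dict                 # animal_id -> AnimalTruth


def _dwell_multiplier(state: int, hour: int) -> float:
    """Hour-of-day dwell modulation: grazing peaks mid-morning and late
    afternoon, resting stretches overnight."""
    if state == GRAZING_STATE:
        peak = math.exp(-((hour - 9.5) ** 2) / 8.0) + math.exp(-((hour - 16.0) ** 2) / 8.0)
        return 0.5 + 1.8 * peak
    if state == RESTING:
        return 2.5 if (hour < 6 or hour >= 20) else 1.0
    return 1.0


_TRANSITIONS = {
    RESTING: ((GRAZING_STATE, 0.8), (TRAVELING, 0.2)),
    GRAZING_STATE: ((RESTING, 0.55), (TRAVELING, 0.45)),
    TRAVELING: ((GRAZING_STATE, 0.7), (RESTING, 0.3)),
}


def _next_state(state: int, rng: np.random.Generator) -> int:
    options, probs = zip(*[(s, p) for s, p in _TRANSITIONS[state]])
    return int(rng.choice(options, p=probs))


def _simulate_animal(
    animal_id: str, cfg: SimConfig, rng: np.random.Generator
) -> AnimalTruth:
    poly = Polygon(cfg.field_polygon)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("field polygon must be simple and closed")
    minx, miny, maxx, maxy = poly.bounds
    n_min = cfg.duration_days * 1440
    start_epoch = to_epoch(cfg.start)

    xs = np.empty(n_min)
    ys = np.empty(n_min)
    states = np.empty(n_min, dtype=np.int8)

    # start somewhere inside the field
    while True:
        pos = (rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        if poly.contains(Point(pos)):
            break
    state = RESTING
    rest_site = pos
    heading = rng.uniform(0.0, 2.0 * math.pi)
    target = None
    hour = int((start_epoch % 86400) // 3600)
    dwell = rng.exponential(cfg.state_config(state).mean_dwell_min
                            * _dwell_multiplier(state, hour))

    def _inside(p):
        return poly.contains(Point(p)) or poly.touches(Point(p))

    normals = rng.standard_normal((n_min, 3))
    uniforms = rng.random(n_min)

    for m in range(n_min):
        xs[m], ys[m] = pos
        states[m] = state
        sc = cfg.state_config(state)
        n1, n2, n3 = normals[m]
        if state == RESTING:
            nx = pos[0] + 0.25 * (rest_site[0] - pos[0]) + sc.step_sd_m * n1
            ny = pos[1] + 0.25 * (rest_site[1] - pos[1]) + sc.step_sd_m * n2
        elif state == GRAZING_STATE:
            heading += 0.7 * n3
            step = abs(sc.step_sd_m * n1) + 0.3 * sc.step_sd_m
            nx = pos[0] + step * math.cos(heading)
            ny = pos[1] + step * math.sin(heading)
        else:  # traveling
            dx, dy = target[0] - pos[0], target[1] - pos[1]
            dist = math.hypot(dx, dy)
            if dist < 15.0:
                dwell = 0.0
                nx, ny = pos
            else:
                speed = min(max(5.0, sc.step_sd_m + 4.0 * n3), dist)
                nx = pos[0] + speed * dx / dist + n1
                ny = pos[1] + speed * dy / dist + n2

        cand = (nx, ny)
        if not _inside(cand):
            # reflect on the bounding box, else stay put
            rx = min(max(nx, 2 * minx - nx), 2 * maxx - nx) if not (minx <= nx <= maxx) else nx
            ry = min(max(ny, 2 * miny - ny), 2 * maxy - ny) if not (miny <= ny <= maxy) else ny
            cand = (rx, ry)
            if not _inside(cand):
                cand = pos
                heading += math.pi
        pos = cand

        dwell -= 1.0
        if dwell <= 0.0:
            state = _next_state(state, rng)
            hour = int(((start_epoch + 60.0 * m) % 86400) // 3600)
            dwell = rng.exponential(
                cfg.state_config(state).mean_dwell_min * _dwell_multiplier(state, hour)
            )
            if state == RESTING:
                rest_site = pos
            elif state == TRAVELING:
                a = cfg.attractors[int(uniforms[m] * len(cfg.attractors))]
                target = (a[0] + 15.0 * rng.standard_normal(),
                          a[1] + 15.0 * rng.standard_normal())

    minute_epochs = start_epoch + 60.0 * np.arange(n_min)
    return AnimalTruth(animal_id, minute_epochs, xs, ys, states)


def _emit_fixes(
    truth: AnimalTruth, cfg: SimConfig, rng: np.random.Generator
) -> list:
    fixes = []
    n_min = truth.minute_epochs.size
    m = 0
    while m < n_min:
        ex = truth.x[m] + cfg.location_error_sd_m * rng.standard_normal()
        ey = truth.y[m] + cfg.location_error_sd_m * rng.standard_normal()
        lat, lon = unproject_coordinates(ex, ey, cfg.reference)
        fixes.append(
            PositionFix(
                animal_id=truth.animal_id,
                time=from_epoch(truth.minute_epochs[m]),
                lat=lat, lon=lon, x=ex, y=ey,
            )
        )
        if truth.state[m] == RESTING:
            m += int(rng.integers(cfg.resting_gap_min[0], cfg.resting_gap_min[1] + 1))
        else:
            m += cfg.fix_interval_active_min
    return fixes


def _emit_activity(
    truth: AnimalTruth, cfg: SimConfig, rng: np.random.Generator
) -> list:
    samples = []
    n_blocks = truth.minute_epochs.size // 30
    shape = cfg.activity_dispersion
    means = np.array([cfg.state_config(s).activity_mean for s in range(3)])
    for b in range(n_blocks):
        block_states = truth.state[b * 30:(b + 1) * 30]
        frac = np.bincount(block_states, minlength=3) / 30.0
        mu = float(frac @ means)
        index = int(round(rng.gamma(shape, mu / shape))) if mu > 0 else 0
        samples.append(
            ActivitySample(
                animal_id=truth.animal_id,
                interval_start=from_epoch(truth.minute_epochs[b * 30]),
                index=index,
            )
        )
    return samples


def _emit_temperature(
    truth: AnimalTruth, cfg: SimConfig, rng: np.random.Generator
) -> list:
    samples = []
    start_epoch = truth.minute_epochs[0]
    n_blocks = truth.minute_epochs.size // 30
    for b in range(n_blocks):
        m = b * 30
        t = truth.minute_epochs[m]
        day = (t - start_epoch) / 86400.0
        hour = (t % 86400) / 3600.0
        temp = (
            cfg.temp_base_c
            + cfg.temp_trend_c_per_day * day
            + cfg.temp_daily_amp_c
            * math.cos(2.0 * math.pi * (hour - cfg.temp_peak_hour) / 24.0)
            + cfg.temp_gradient_c_per_m * (truth.y[m] - 150.0)
            + cfg.temp_noise_sd_c * rng.standard_normal()
        )
        samples.append(
            TemperatureSample(truth.animal_id, from_epoch(t), float(temp))
        )
    return samples


def simulate_herd(config: Optional[SimConfig] = None) -> SyntheticDataset:
    """Simulate the full herd; identical config (incl. seed) gives
    identical output."""
    cfg = config or SimConfig()
    root = np.random.SeedSequence(cfg.seed)
    streams = root.spawn(cfg.n_animals)
    fixes, activity, temperature = [], [], []
    truth: dict[str, AnimalTruth] = {}
    for i in range(cfg.n_animals):
        rng = np.random.default_rng(streams[i])
        animal_id = f"cow{i + 1:02d}"
        t = _simulate_animal(animal_id, cfg, rng)
        truth[animal_id] = t
        fixes.extend(_emit_fixes(t, cfg, rng))
        activity.extend(_emit_activity(t, cfg, rng))
        temperature.extend(_emit_temperature(t, cfg, rng))
    return SyntheticDataset(cfg, fixes, activity, temperature, truth)


def observation_minutes(
    dataset: SyntheticDataset,
    sessions: Optional[Sequence[tuple[datetime, datetime]]] = None,
    observer_id: str = "sim-observer",
) -> list:
    """Derive per-minute behaviour labels from the true state sequence.

    Default sessions: 08:00-17:00 UTC on the first 8 simulated days,
    mirroring an in-person observation campaign.
    """
    cfg = dataset.config
    if sessions is None:
        sessions = []
        for d in range(min(8, cfg.duration_days)):
            day = cfg.start + timedelta(days=d)
            sessions.append((day + timedelta(hours=8), day + timedelta(hours=17)))
    out = []
    for animal_id, truth in dataset.truth.items():
        t0 = truth.minute_epochs[0]
        for s_start, s_end in sessions:
            m0 = int((to_epoch(s_start) - t0) // 60)
            m1 = int((to_epoch(s_end) - t0) // 60)
            for m in range(max(m0, 0), min(m1, truth.minute_epochs.size)):
                label = "grazing" if truth.state[m] == GRAZING_STATE else "non_grazing"
                out.append(
                    ObservationMinute(
                        animal_id, from_epoch(truth.minute_epochs[m]),
                        label, observer_id,
                    )
                )
    return out


def simulate_brownian_track(
    sigma2_m: float,
    n_fixes: int,
    dt: float = 900.0,
    error_sd: float = 5.0,
    seed: int = 0,
    animal_id: str = "sim",
    start_xy: tuple[float, float] = (0.0, 0.0),
    start: Optional[datetime] = None,
    reference: ReferencePoint = DEFAULT_REFERENCE,
) -> list:
    """Pure Brownian-motion track with Gaussian observation error."""
    if sigma2_m < 0 or n_fixes < 1:
        raise ValueError("sigma2_m must be >= 0 and n_fixes >= 1")
    rng = np.random.default_rng(seed)
    start = start or datetime(2023, 9, 29, tzinfo=timezone.utc)
    steps = rng.standard_normal((n_fixes - 1, 2)) * math.sqrt(sigma2_m * dt)
    true = np.vstack([[start_xy], steps]).cumsum(axis=0)
    obs = true + error_sd * rng.standard_normal((n_fixes, 2))
    t0 = to_epoch(start)
    fixes = []
    for k in range(n_fixes):
        lat, lon = unproject_coordinates(obs[k, 0], obs[k, 1], reference)
        fixes.append(
            PositionFix(animal_id, from_epoch(t0 + k * dt), lat, lon,
                        x=float(obs[k, 0]), y=float(obs[k, 1]))
        )
    return fixes


def true_occupancy(
    dataset: SyntheticDataset,
    grid: GridSpec,
    window: Optional[TimeWindow] = None,
) -> Raster:
    """Ground-truth occupancy: 60 s per minute credited to the containing
    cell, pooled over all animals."""
    window = window or TimeWindow.full()
    values = np.zeros((grid.nx, grid.ny))
    for truth in dataset.truth.values():
        keep = window.mask(truth.minute_epochs)
        ix, iy, ok = locate_cells(grid, truth.x, truth.y)
        sel = keep & ok
        np.add.at(values, (ix[sel], iy[sel]), 60.0)
    return Raster(grid, values, units="seconds")
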