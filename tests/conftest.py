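from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest

from herdmap.grid import make_grid
from herdmap.ingest import ActivitySample, PositionFix
from herdmap.simulate import SimConfig, observation_minutes, simulate_herd

UTC = timezone.utc
T0 = datetime(2023, 9, 29, tzinfo=UTC)


def fix(animal: str, seconds: float, x: float, y: float) -> PositionFix:
    """Projected fix at T0 + seconds, with dummy but valid lat/lon."""
    return PositionFix(animal, T0 + timedelta(seconds=seconds),
                       lat=51.9, lon=0.91, x=x, y=y)


def sample(animal: str, seconds: float, index: int,
           length: float = 1800.0) -> ActivitySample:
    return ActivitySample(animal, T0 + timedelta(seconds=seconds), index,
                          interval_length=length)


@pytest.fixture(scope="session")
def default_herd():
    """The full default synthetic herd: 3 animals, 58 days, seed 42."""
    return simulate_herd(SimConfig(seed=42))


@pytest.fixture(scope="session")
def default_grid(default_herd):
    return make_grid(default_herd.fixes, cell_size=15.0, pad=60.0)


@pytest.fixture(scope="session")
def small_herd():
    """A quick herd for behavioural checks: 2 animals, 10 days."""
    return simulate_herd(SimConfig(seed=7, n_animals=2, duration_days=10))


@pytest.fixture(scope="session")
def small_observations(small_herd):
    return observation_minutes(small_herd)
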