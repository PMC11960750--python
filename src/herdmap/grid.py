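"""Spatial grid definition, point location, raster containers and raster I/O.

Cells are half-open squares ``[origin + i*d, origin + (i+1)*d)`` on each
axis with 0-based ``(ix, iy)`` indices.  Rasters are dense ``(nx, ny)``
arrays; NaN marks cells with no data (distinct from an observed zero).
The canonical on-disk raster format is a headered CSV of ``ix, iy, value``
with a JSON sidecar holding the grid definition.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

#: units whose cell values are non-negative accumulations
MASS_UNITS = {"seconds", "activity counts", "probability"}


@dataclass(frozen=True)
class GridSpec:
    origin_x: float
    origin_y: float
    cell_size: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell per axis")

    @property
    def x_edges(self) -> np.ndarray:
        return self.origin_x + self.cell_size * np.arange(self.nx + 1)

    @property
    def y_edges(self) -> np.ndarray:
        return self.origin_y + self.cell_size * np.arange(self.ny + 1)

    def cell_center(self, ix: int, iy: int) -> tuple[float, float]:
        return (
            self.origin_x + (ix + 0.5) * self.cell_size,
            self.origin_y + (iy + 0.5) * self.cell_size,
        )

    @property
    def cell_area(self) -> float:
        return self.cell_size * self.cell_size

    def to_dict(self) -> dict:
        return {
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "cell_size": self.cell_size,
            "nx": self.nx,
            "ny": self.ny,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GridSpec":
        return cls(
            float(d["origin_x"]), float(d["origin_y"]), float(d["cell_size"]),
            int(d["nx"]), int(d["ny"]),
        )


def make_grid(fixes: Sequence, cell_size: float = 15.0, pad: float = 0.0) -> GridSpec:
    """Build the minimal grid covering all projected fixes plus *pad* metres.

    The origin is snapped to a multiple of *cell_size* so that the
    projected-space point (0, 0) always falls on a cell corner, making
    grids reproducible run-to-run regardless of data extent.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if pad < 0:
        raise ValueError("pad must be non-negative")
    xs = np.asarray([f.x for f in fixes], dtype=float)
    ys = np.asarray([f.y for f in fixes], dtype=float)
    if xs.size == 0:
        raise ValueError("cannot build a grid from an empty fix list")
    if np.isnan(xs).any() or np.isnan(ys).any():
        raise ValueError("fixes must be projected before gridding")

    def _axis(vals: np.ndarray) -> tuple[float, int]:
        lo = math.floor((vals.min() - pad) / cell_size) * cell_size
        n = int(math.floor((vals.max() + pad - lo) / cell_size)) + 1
        return lo, n

    ox, nx = _axis(xs)
    oy, ny = _axis(ys)
    return GridSpec(ox, oy, cell_size, nx, ny)


def locate_cell(grid: GridSpec, x: float, y: float) -> Optional[tuple[int, int]]:
    """Half-open cell assignment; ``None`` marks an out-of-bounds point."""
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError("coordinates must be finite")
    ix = math.floor((x - grid.origin_x) / grid.cell_size)
    iy = math.floor((y - grid.origin_y) / grid.cell_size)
    if 0 <= ix < grid.nx and 0 <= iy < grid.ny:
        return int(ix), int(iy)
    return None


def locate_cells(
    grid: GridSpec, xs: np.ndarray, ys: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`locate_cell`; returns (ix, iy, in_bounds mask)."""
    ix = np.floor((np.asarray(xs, float) - grid.origin_x) / grid.cell_size).astype(int)
    iy = np.floor((np.asarray(ys, float) - grid.origin_y) / grid.cell_size).astype(int)
    ok = (ix >= 0) & (ix < grid.nx) & (iy >= 0) & (iy < grid.ny)
    return ix, iy, ok


@dataclass
class Raster:
    """Grid of values over the field; NaN entries are no-data."""

    grid: GridSpec
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.nx, self.grid.ny):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.nx}, {self.grid.ny})"
            )
        if self.units in MASS_UNITS:
            finite = self.values[np.isfinite(self.values)]
            if finite.size and finite.min() < -1e-12:
                raise ValueError(f"negative entries in {self.units!r} raster")

    def total(self) -> float:
        return float(np.nansum(self.values))


@dataclass
class ProbabilityRaster(Raster):
    units: str = "probability"

    def __post_init__(self) -> None:
        self.units = "probability"
        super().__post_init__()
        total = float(np.nansum(self.values))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probability raster sums to {total}, not 1")


def normalize_raster(r: Raster) -> ProbabilityRaster:
    """Divide by total mass; NaN (no-data) cells contribute zero mass."""
    vals = np.nan_to_num(r.values, nan=0.0)
    total = vals.sum()
    if total <= 0:
        raise ValueError("cannot normalize a raster with no mass")
    return ProbabilityRaster(r.grid, vals / total)


@dataclass
class RegionMask:
    """Per-cell region labels on a grid (e.g. upper vs lower field)."""

    grid: GridSpec
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (self.grid.nx, self.grid.ny):
            raise ValueError("labels shape does not match grid")

    @property
    def region_names(self) -> list[str]:
        return sorted({str(v) for v in self.labels.ravel()})

    @classmethod
    def from_polygons(
        cls, grid: GridSpec, polygons: Mapping[str, object], default: str = "other"
    ) -> "RegionMask":
        """Label each cell by the polygon containing its centre point."""
        import shapely

        cx = grid.origin_x + (np.arange(grid.nx) + 0.5) * grid.cell_size
        cy = grid.origin_y + (np.arange(grid.ny) + 0.5) * grid.cell_size
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        labels = np.full((grid.nx, grid.ny), default, dtype=object)
        for name, poly in polygons.items():
            inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel())
            labels.ravel()[inside] = name
        return cls(grid, labels)


def write_raster(raster: Raster, csv_path: str, json_path: Optional[str] = None) -> None:
    if json_path is None:
        json_path = str(csv_path) + ".json"
    with open(csv_path, "w") as fh:
        fh.write("ix,iy,value\n")
        for ix in range(raster.grid.nx):
            for iy in range(raster.grid.ny):
                v = raster.values[ix, iy]
                fh.write(f"{ix},{iy},{'' if math.isnan(v) else repr(float(v))}\n")
    meta = {"grid": raster.grid.to_dict(), "units": raster.units}
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_raster(csv_path: str, json_path: Optional[str] = None) -> Raster:
    import pandas as pd

    if json_path is None:
        json_path = str(csv_path) + ".json"
    with open(json_path) as fh:
        meta = json.load(fh)
    grid = GridSpec.from_dict(meta["grid"])
    df = pd.read_csv(csv_path)
    values = np.full((grid.nx, grid.ny), np.nan)
    values[df["ix"].to_numpy(int), df["iy"].to_numpy(int)] = df["value"].to_numpy(float)
    return Raster(grid, values, units=meta.get("units", ""))
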