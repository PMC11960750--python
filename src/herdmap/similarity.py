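"""Core/full-range isopleths, per-region range summaries, and
Bhattacharyya-coefficient comparisons between normalized surfaces.

The Bhattacharyya coefficient defaults to the radical form
``BC = sum_i sqrt(P_i Q_i)``, which is the form whose extreme values
match the usual interpretation (1 for identical distributions, 0 for
disjoint support).  ``form="product"`` computes the plain product sum
``sum_i P_i Q_i`` for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .grid import GridSpec, ProbabilityRaster, RegionMask


@dataclass
class IsoplethResult:
    """Highest-density cell set cumulatively enclosing at least *level*."""

    level: float
    cells: list[tuple[int, int]]
    mass: float
    area_m2: float


def volume_isopleth(p: ProbabilityRaster, level: float) -> IsoplethResult:
    """Greedy highest-density isopleth.

    Cells are ranked by density descending (ties broken by (ix, iy)
    lexicographic order) and accumulated until the enclosed mass first
    reaches *level*.  Zero-density cells are never included.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be strictly between 0 and 1")
    if not isinstance(p, ProbabilityRaster):
        raise ValueError("volume_isopleth requires a normalized raster")
    vals = np.nan_to_num(p.values, nan=0.0)
    ix, iy = np.unravel_index(np.arange(vals.size), vals.shape)
    order = np.lexsort((iy, ix, -vals.ravel()))
    dens = vals.ravel()[order]
    cum = np.cumsum(dens)
    # first position where cumulative mass reaches the level
    k = int(np.searchsorted(cum, level - 1e-12)) + 1
    k = min(k, int((dens > 0).sum()))
    cells = [(int(ix[o]), int(iy[o])) for o in order[:k]]
    return IsoplethResult(
        level=level,
        cells=cells,
        mass=float(cum[k - 1]) if k else 0.0,
        area_m2=k * p.grid.cell_area,
    )


def bhattacharyya_coefficient(
    p: ProbabilityRaster, q: ProbabilityRaster, form: str = "radical"
) -> float:
    """Overlap between two normalized surfaces on the same grid, in [0, 1]."""
    if p.grid != q.grid:
        raise ValueError("rasters are on different grids")
    pv = np.nan_to_num(p.values, nan=0.0)
    qv = np.nan_to_num(q.values, nan=0.0)
    if form == "radical":
        return float(np.sum(np.sqrt(pv * qv)))
    if form == "product":
        return float(np.sum(pv * qv))
    raise ValueError(f"unknown BC form {form!r}")


def range_summary(
    p: ProbabilityRaster,
    levels: Sequence[float] = (0.5, 0.95),
    mask: Optional[RegionMask] = None,
) -> pd.DataFrame:
    """Tabulate isopleth cell counts and areas, optionally split by region.

    The isopleth is computed on the full surface first, then its cells are
    tallied per region, so region totals sum to the whole-field count.
    """
    if mask is not None and mask.grid != p.grid:
        raise ValueError("region mask is on a different grid")
    regions = mask.region_names if mask is not None else ["all"]
    rows = []
    for level in levels:
        iso = volume_isopleth(p, level)
        counts = {r: 0 for r in regions}
        for ix, iy in iso.cells:
            r = str(mask.labels[ix, iy]) if mask is not None else "all"
            counts[r] = counts.get(r, 0) + 1
        for r in regions:
            rows.append({
                "level": level,
                "region": r,
                "cells": counts[r],
                "area_m2": counts[r] * p.grid.cell_area,
            })
    return pd.DataFrame(rows)


def comparison_matrix(
    rasters: Mapping[str, ProbabilityRaster], form: str = "radical"
) -> pd.DataFrame:
    """Symmetric BC matrix across a named set of surfaces."""
    names = list(rasters)
    grids = {r.grid for r in rasters.values()}
    if len(grids) > 1:
        raise ValueError("all rasters must share one grid")
    mat = np.eye(len(names))
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            bc = bhattacharyya_coefficient(rasters[a], rasters[names[j]], form=form)
            mat[i, j] = mat[j, i] = bc
    return pd.DataFrame(mat, index=names, columns=names)


def isopleth_geojson(iso: IsoplethResult, grid: GridSpec,
                     properties: Optional[dict] = None) -> dict:
    """Isopleth cell set as a GeoJSON feature (projected metres)."""
    import shapely
    from shapely.geometry import box, mapping

    cs = grid.cell_size
    boxes = [
        box(grid.origin_x + ix * cs, grid.origin_y + iy * cs,
            grid.origin_x + (ix + 1) * cs, grid.origin_y + (iy + 1) * cs)
        for ix, iy in iso.cells
    ]
    geom = shapely.union_all(boxes) if boxes else shapely.Polygon()
    props = {"level": iso.level, "mass": iso.mass, "area_m2": iso.area_m2}
    props.update(properties or {})
    return {"type": "Feature", "geometry": mapping(geom), "properties": props}
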