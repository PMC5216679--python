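"""Derived predictors: old-forest connectivity, wetness, slope orientation.

Connectivity measures kernel-weighted dispersal input from surrounding
old forest; the wetness index is the classic ln(a / tan(beta))
topographic wetness index from single-direction (D8) flow routing; the
steepness/orientation value sin(slope) * cos(aspect-from-north) is
positive on steep north-facing slopes and zero on flat ground.
Standardization divides by the standard deviation without centering so
coefficient magnitudes are comparable across covariates while zeros
keep their meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = ["ConnectivityConfig", "connectivity", "wetness_index", "northness", "standardize"]


@dataclass
class ConnectivityConfig:
    """Settings for the old-forest connectivity kernel.

    ``mean_dispersal_km`` sets the e-folding scale alpha of the
    negative-exponential kernel exp(-d / alpha) in kilometres (1, 5 and
    10 km are the values typically examined). Sources are cells (or
    plots) with age >= ``old_forest_age_threshold``, weighted by the
    ``source_weight`` covariate; contributions beyond
    ``truncation_radius`` * alpha are dropped.
    """

    mean_dispersal_km: float = 1.0
    old_forest_age_threshold: float = 100.0
    truncation_radius: float = 8.0
    source_weight: str = "spruce_volume"

    def __post_init__(self) -> None:
        if self.mean_dispersal_km <= 0:
            raise ValueError("mean_dispersal_km must be positive")
        if self.truncation_radius < 1:
            raise ValueError("truncation_radius must be >= 1")


def connectivity(cells, config: ConnectivityConfig | None = None,
                 age_column: str = "forest_age") -> np.ndarray:
    """Kernel-weighted old-forest source strength per cell or plot.

    S_i = sum over source cells j != i with age_j >= threshold of
    w_j * exp(-d_ij / alpha), alpha = mean_dispersal_km * 1000 m.
    Coordinates come from ``x``/``y`` columns (metres) or, for gridded
    landscapes, from ``row``/``col`` times ``cell_size_m``.
    """
    config = config or ConnectivityConfig()
    table = getattr(cells, "cells", cells)
    xy = _coords_m(table, getattr(cells, "cell_size_m", None))
    alpha = config.mean_dispersal_km * 1000.0
    radius = config.truncation_radius * alpha
    age = np.asarray(table[age_column], dtype=float)
    w = np.asarray(table[config.source_weight], dtype=float)
    is_source = age >= config.old_forest_age_threshold
    out = np.zeros(len(table))
    if not is_source.any():
        return out
    src_xy = xy[is_source]
    src_w = w[is_source]
    src_idx = np.flatnonzero(is_source)
    tree = cKDTree(src_xy)
    neighbours = tree.query_ball_point(xy, r=radius)
    for i, nbrs in enumerate(neighbours):
        if not nbrs:
            continue
        nbrs = np.asarray(nbrs)
        d = np.linalg.norm(src_xy[nbrs] - xy[i], axis=1)
        keep = src_idx[nbrs] != i  # a source never contributes to itself
        out[i] = np.sum(src_w[nbrs[keep]] * np.exp(-d[keep] / alpha))
    return out


def _coords_m(table: pd.DataFrame, cell_size_m: float | None) -> np.ndarray:
    if "x" in table.columns and "y" in table.columns:
        return np.column_stack([np.asarray(table["x"], float), np.asarray(table["y"], float)])
    if "row" in table.columns and "col" in table.columns:
        size = 100.0 if cell_size_m is None else float(cell_size_m)
        return np.column_stack([np.asarray(table["col"], float) * size,
                                np.asarray(table["row"], float) * size])
    raise ValueError("no coordinates: need x/y or row/col columns")


# ---------------------------------------------------------------------------
# terrain


_D8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def wetness_index(elevation_grid, cell_size_m: float = 100.0,
                  slope_floor: float = 1e-4) -> np.ndarray:
    """Topographic wetness index ln(a / tan(beta)) on a rectangular grid.

    Flow accumulation ``a`` (specific catchment area, m) uses D8
    routing: every cell drains to its steepest-descent neighbour;
    contributing area is resolved by processing cells from high to low
    elevation. tan(beta) is floored at ``slope_floor`` so flat terrain
    yields a finite, constant index.
    """
    z = _as_grid(elevation_grid)
    nr, nc = z.shape
    slope = _slope_tan(z, cell_size_m)
    slope = np.maximum(slope, slope_floor)

    # steepest-descent receiver per cell (-1: pit / flat, no receiver)
    receiver = np.full((nr, nc), -1, dtype=np.int64)
    for r in range(nr):
        for c in range(nc):
            best_drop = 0.0
            best = -1
            for dr, dc in _D8:
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc:
                    dist = cell_size_m * np.hypot(dr, dc)
                    drop = (z[r, c] - z[rr, cc]) / dist
                    if drop > best_drop:
                        best_drop = drop
                        best = rr * nc + cc
            receiver[r, c] = best
    area = np.full(nr * nc, cell_size_m * cell_size_m)
    order = np.argsort(z.ravel())[::-1]  # high to low: donors before receivers
    flat_receiver = receiver.ravel()
    for idx in order:
        rec = flat_receiver[idx]
        if rec >= 0:
            area[rec] += area[idx]
    specific_area = area.reshape(nr, nc) / cell_size_m
    return np.log(specific_area / slope)


def northness(elevation_grid, cell_size_m: float = 100.0) -> np.ndarray:
    """sin(slope) * cos(aspect from north): steep north-facing slopes > 0.

    Row 0 is the northern edge, so elevation increasing with row number
    means the terrain rises southward. Flat cells return exactly 0;
    values are bounded by [-1, 1].
    """
    z = _as_grid(elevation_grid)
    dz_drow, dz_dcol = np.gradient(z, cell_size_m)
    dz_dnorth = -dz_drow
    grad = np.hypot(dz_dnorth, dz_dcol)
    slope = np.arctan(grad)
    # downslope unit vector's northward component = -dz_dnorth / |grad|
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_aspect = np.where(grad > 0, -dz_dnorth / np.where(grad > 0, grad, 1.0), 0.0)
    return np.sin(slope) * cos_aspect


def _as_grid(elevation_grid) -> np.ndarray:
    z = np.asarray(elevation_grid, dtype=float)
    if z.ndim != 2 or z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("elevation grid must be at least 3x3")
    if not np.all(np.isfinite(z)):
        raise ValueError("elevation grid contains non-finite values")
    return z


def _slope_tan(z: np.ndarray, cell_size_m: float) -> np.ndarray:
    dzdr, dzdc = np.gradient(z, cell_size_m)
    return np.hypot(dzdr, dzdc)


# ---------------------------------------------------------------------------
# standardization


def standardize(table: pd.DataFrame, columns: list[str]) -> tuple[pd.DataFrame, pd.Series]:
    """Divide each column by its standard deviation (no centering).

    Returns the transformed copy and the scale factors; multiplying a
    standardized column by its factor restores the original values.
    Forecast-time covariates must be scaled with the training factors.
    """
    out = table.copy()
    scales = {}
    for col in columns:
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in table")
        sd = float(np.asarray(table[col], dtype=float).std(ddof=0))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {col!r} has zero standard deviation")
        out[col] = table[col] / sd
        scales[col] = sd
    return out, pd.Series(scales, name="scale")


def apply_scale(table: pd.DataFrame, scale_factors: pd.Series) -> pd.DataFrame:
    """Scale new data with training-time factors (columns not listed pass through)."""
    out = table.copy()
    for col, sd in scale_factors.items():
        if col in out.columns:
            out[col] = out[col] / sd
    return out
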