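"""Spatiotemporal summaries: zonal statistics, monthly series, histograms.

All statistics are area-aware: cell areas on a geographic grid shrink with
latitude, so class means are area-weighted by default and totals integrate
value * cell area.  Totals carry a unit scale (default 1e-6) converting
e.g. gC m^-2 * km^2 into TgC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import Grid, GridStack, GeoRef, ensure_aligned

logger = logging.getLogger(__name__)

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088

#: gC m^-2 * km^2 -> TgC (1 gC/m2 over 1 km2 = 1e6 gC; 1 Tg = 1e12 g).
GC_M2_KM2_TO_TG = 1e-6


@dataclass
class PartitionStats:
    """One row of a zonal summary table."""

    class_label: str
    area_km2: float
    area_pct: float
    mean_value: float
    max_value: float
    total: float
    total_pct: float


def cell_area_grid(georef: GeoRef, shape: tuple[int, int]) -> Grid:
    """Spherical cell areas (km^2) for a north-up geographic grid.

    Each cell spans dx degrees of longitude between latitudes phi_top and
    phi_bottom; its area is R^2 * dlambda * (sin(phi_top) - sin(phi_bottom)).
    """
    if not georef.is_geographic:
        raise ValueError(f"cell areas require a geographic CRS, got {georef.crs!r}")
    rows, cols = shape
    lat_top = np.deg2rad(georef.north - np.arange(rows) * georef.dy)
    lat_bot = np.deg2rad(georef.north - (np.arange(rows) + 1) * georef.dy)
    dlam = np.deg2rad(georef.dx)
    band = EARTH_RADIUS_KM**2 * dlam * (np.sin(lat_top) - np.sin(lat_bot))
    values = np.repeat(band[:, None], cols, axis=1)
    return Grid(values, georef, units="km2")


def partition_stats(
    values: Grid,
    classes: Grid,
    areas: Grid,
    labels: dict[int, str] | None = None,
    total_scale: float = GC_M2_KM2_TO_TG,
    area_weighted_mean: bool = True,
) -> list[PartitionStats]:
    """Per-class area, mean, max and total of a value raster.

    Cells masked in either the value or class raster are excluded from all
    statistics.  ``total = sum(value * cell area) * total_scale``;
    percentages are relative to the unmasked whole.  Empty classes are
    omitted with a warning.
    """
    ensure_aligned(values, classes, areas, names=["values", "classes", "areas"])
    valid = ~(values.mask | classes.mask)
    if not valid.any():
        raise ValueError("no unmasked cells to summarise")

    cls = classes.values[valid].astype(int)
    val = values.values[valid]
    area = areas.values[valid]

    total_area = float(area.sum())
    grand_total = float((val * area).sum())

    rows: list[PartitionStats] = []
    for code in np.unique(cls):
        sel = cls == code
        if not sel.any():
            logger.warning("partition_stats: class %s empty, omitted", code)
            continue
        a = float(area[sel].sum())
        if area_weighted_mean:
            mean = float((val[sel] * area[sel]).sum() / a)
        else:
            mean = float(val[sel].mean())
        tot = float((val[sel] * area[sel]).sum())
        label = labels.get(int(code), str(int(code))) if labels else str(int(code))
        rows.append(
            PartitionStats(
                class_label=label,
                area_km2=a,
                area_pct=100.0 * a / total_area,
                mean_value=mean,
                max_value=float(val[sel].max()),
                total=tot * total_scale,
                total_pct=100.0 * tot / grand_total if grand_total != 0 else 0.0,
            )
        )
    return rows


def classify_elevation(dem: Grid, breaks: list[float]) -> tuple[Grid, dict[int, str]]:
    """Classify a DEM into half-open elevation bands [lo, hi).

    Band 0 is below the first break, band k is above the last; a cell
    exactly on a break belongs to the band above it.
    """
    b = list(breaks)
    if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
        raise ValueError("elevation breaks must be strictly increasing")
    codes = np.digitize(dem.values, b, right=False)
    labels = {0: f"<{b[0]:g}"}
    for i in range(len(b) - 1):
        labels[i + 1] = f"{b[i]:g}-{b[i + 1]:g}"
    labels[len(b)] = f">{b[-1]:g}"
    return Grid(codes.astype(float), dem.georef, dem.mask.copy(), units=""), labels


def elevation_band_stats(
    values: Grid,
    dem: Grid,
    breaks: list[float],
    areas: Grid,
    total_scale: float = GC_M2_KM2_TO_TG,
    area_weighted_mean: bool = True,
) -> list[PartitionStats]:
    """Zonal statistics of a value raster over elevation bands of a DEM."""
    classes, labels = classify_elevation(dem, breaks)
    return partition_stats(
        values, classes, areas, labels=labels,
        total_scale=total_scale, area_weighted_mean=area_weighted_mean,
    )


def monthly_series(
    stack: GridStack,
    areas: Grid,
    mask: Grid | np.ndarray | None = None,
    total_scale: float = GC_M2_KM2_TO_TG,
) -> tuple[np.ndarray, np.ndarray]:
    """Area-weighted monthly totals and means over an optional region mask.

    Returns (totals, means), each of length 12; totals are scaled by
    ``total_scale`` (default gC m^-2 km^2 -> TgC), means are per-cell-area
    averages in the stack's own units.
    """
    region = np.ones(stack.shape, dtype=bool)
    if mask is not None:
        region = ~mask.mask & mask.values.astype(bool) if isinstance(mask, Grid) else np.asarray(mask, bool)
    if not region.any():
        raise ValueError("empty region mask")
    totals = np.empty(12)
    means = np.empty(12)
    for m in range(12):
        valid = region & ~stack.mask[m]
        if not valid.any():
            totals[m] = np.nan
            means[m] = np.nan
            continue
        v = stack.values[m][valid]
        a = areas.values[valid]
        totals[m] = (v * a).sum() * total_scale
        means[m] = (v * a).sum() / a.sum()
    return totals, means


def histogram_stats(
    grid: Grid, bin_edges: list[float], mask: np.ndarray | None = None
) -> dict:
    """Histogram of unmasked cell values with [lo, hi) bins, last bin closed.

    Returns dict with ``counts`` (len = len(bin_edges) - 1), ``bin_edges``,
    and summary ``min``/``max``/``mean`` over the counted cells.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    valid = ~grid.mask
    if mask is not None:
        valid &= np.asarray(mask, bool)
    vals = grid.values[valid]
    # np.histogram uses [lo, hi) with the last bin closed, matching the contract
    counts, _ = np.histogram(vals, bins=edges)
    in_range = vals[(vals >= edges[0]) & (vals <= edges[-1])]
    return {
        "counts": counts,
        "bin_edges": edges,
        "n": int(vals.size),
        "min": float(vals.min()) if vals.size else np.nan,
        "max": float(vals.max()) if vals.size else np.nan,
        "mean": float(vals.mean()) if vals.size else np.nan,
        "n_in_range": int(in_range.size),
    }
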