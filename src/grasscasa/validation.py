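"""Validation of modeled NPP against in-situ dry-yield measurements.

Field surveys clip aboveground dry biomass (g m^-2); the model reports
total NPP carbon (gC m^-2).  The comparison chain is

    aboveground carbon = dry_yield * carbon_fraction (0.45)
    total carbon       = aboveground carbon * (1 + R)

with R the belowground/aboveground (root:shoot) biomass ratio of the
point's grassland type.  Each converted observation is paired with the
modeled NPP of the raster cell containing it, and the relative error
statistic

    Error % = mean(|X1 - X2| / X2) * 100,   Precision % = 100 - Error %

is computed per grassland type and pooled.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np

from .casa import annual_sum
from .grids import Grid, GridStack
from .params import ModelParams

logger = logging.getLogger(__name__)


@dataclass
class InSituPoint:
    """One field sample: location, date, grassland type, clipped dry yield."""

    point_id: str
    lon: float
    lat: float
    date: dt.date
    grassland_type: str
    dry_yield: float

    def __post_init__(self) -> None:
        if self.dry_yield < 0:
            raise ValueError(f"point {self.point_id}: dry_yield must be >= 0")


@dataclass
class ValidationRow:
    """One row of the validation report."""

    grassland_type: str
    n_points: int
    error_pct: float
    precision_pct: float


def dry_yield_to_npp(
    dry_yield: float, grassland_type: str, params: ModelParams
) -> float:
    """Convert clipped aboveground dry yield (g m^-2) to total NPP carbon (gC m^-2).

    Aboveground carbon is dry_yield * 0.45; the unmeasured belowground part
    is allocated with the type's root:shoot ratio R (belowground/aboveground),
    so total = aboveground * (1 + R).
    """
    if grassland_type not in params.root_shoot:
        raise KeyError(
            f"unknown grassland type {grassland_type!r}; known types: "
            f"{sorted(params.root_shoot)}"
        )
    ratio = params.root_shoot[grassland_type]
    aboveground_c = dry_yield * params.carbon_fraction
    return aboveground_c * (1.0 + ratio)


def extract_modeled_at_points(
    npp: GridStack,
    points: list[InSituPoint],
    period: str | int = "annual",
) -> tuple[list[float], list[InSituPoint]]:
    """Read modeled NPP at each point's nearest cell.

    ``period`` selects the annual layer (default) or a single month (1..12).
    Points outside the raster extent or on masked cells are excluded and
    logged.  Returns (modeled values, retained points) in matching order.
    """
    if period == "annual":
        layer: Grid = annual_sum(npp)
    else:
        layer = npp.month(int(period))

    rows, cols = layer.shape
    modeled: list[float] = []
    kept: list[InSituPoint] = []
    for pt in points:
        r, c = layer.georef.rowcol(pt.lon, pt.lat)
        if not (0 <= r < rows and 0 <= c < cols):
            logger.warning("point %s outside raster extent, excluded", pt.point_id)
            continue
        if layer.mask[r, c]:
            logger.warning("point %s falls on a masked cell, excluded", pt.point_id)
            continue
        modeled.append(float(layer.values[r, c]))
        kept.append(pt)
    return modeled, kept


def validation_error(modeled: list[float], observed: list[float]) -> tuple[float, float]:
    """Mean absolute relative error and its complement, both in percent.

    Error = (sum over points of |X1 - X2| / X2) / N * 100, with X1 modeled
    and X2 observed; Precision = 100 - Error.  Points with X2 = 0 are
    excluded with a warning (the statistic divides by X2).
    """
    if len(modeled) != len(observed):
        raise ValueError("modeled and observed must have equal length")
    x1 = np.asarray(modeled, dtype=float)
    x2 = np.asarray(observed, dtype=float)
    nonzero = x2 != 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.warning("validation_error: %d points with observed value 0 excluded", n_dropped)
    x1, x2 = x1[nonzero], x2[nonzero]
    if x1.size == 0:
        raise ValueError("no usable validation points (all observed values were 0)")
    error = float(np.mean(np.abs(x1 - x2) / x2) * 100.0)
    return error, 100.0 - error


def validate_by_type(
    points: list[InSituPoint],
    npp: GridStack,
    params: ModelParams | None = None,
    period: str | int = "annual",
) -> list[ValidationRow]:
    """Per-type and pooled validation report.

    Converts each point's dry yield to total NPP carbon, pairs it with the
    modeled NPP at its cell, groups by grassland type and computes the
    error/precision statistic per group plus a pooled "Total" row.  Points
    of a type absent from the root:shoot table are excluded with a warning.
    """
    params = params or ModelParams()
    known = [p for p in points if p.grassland_type in params.root_shoot]
    for p in points:
        if p.grassland_type not in params.root_shoot:
            logger.warning(
                "point %s: grassland type %r not in root:shoot table, excluded",
                p.point_id, p.grassland_type,
            )
    modeled, kept = extract_modeled_at_points(npp, known, period=period)
    observed = [dry_yield_to_npp(p.dry_yield, p.grassland_type, params) for p in kept]

    rows: list[ValidationRow] = []
    pooled_m: list[float] = []
    pooled_o: list[float] = []
    for gtype in sorted({p.grassland_type for p in kept}):
        m = [v for v, p in zip(modeled, kept) if p.grassland_type == gtype]
        o = [v for v, p in zip(observed, kept) if p.grassland_type == gtype]
        usable = [(x1, x2) for x1, x2 in zip(m, o) if x2 != 0]
        if not usable:
            logger.warning("grassland type %r: no usable points, omitted", gtype)
            continue
        err, prec = validation_error([u[0] for u in usable], [u[1] for u in usable])
        rows.append(ValidationRow(gtype, len(usable), err, prec))
        pooled_m.extend(u[0] for u in usable)
        pooled_o.extend(u[1] for u in usable)

    if not pooled_m:
        raise ValueError("no usable validation points")
    err, prec = validation_error(pooled_m, pooled_o)
    rows.append(ValidationRow("Total", len(pooled_m), err, prec))
    return rows
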