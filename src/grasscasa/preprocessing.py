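"""Preprocessing: compositing, temporal gap-filling, temperature interpolation.

Turns raw inputs into the aligned monthly stacks the model consumes:

* 8-day (or irregular) composite series are aggregated to monthly means,
  weighting each period by the number of days it overlaps the month;
* missing months are filled per cell with a cubic spline along the time
  axis, clamped to the nearest observation outside the observed span;
* station air temperatures are gridded with an elevation-aware two-step
  scheme: a least-squares lapse-rate regression on elevation followed by a
  thin-plate spline interpolation of the residuals over lon/lat.
"""

from __future__ import annotations

import calendar
import datetime as dt
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, RBFInterpolator

from .grids import Grid, GridStack, ensure_aligned

logger = logging.getLogger(__name__)


@dataclass
class CompositeSeries:
    """A sequence of fixed-period composite layers (e.g. 8-day FPAR).

    ``layers[i]`` covers ``period_length_days[i]`` days starting at
    ``period_starts[i]``.  Periods must be non-overlapping and ascending,
    and all layers must share one georeference.
    """

    layers: list[Grid]
    period_starts: list[dt.date]
    period_length_days: list[int]

    def __post_init__(self) -> None:
        n = len(self.layers)
        if not (len(self.period_starts) == len(self.period_length_days) == n):
            raise ValueError("layers, period_starts, period_length_days must match in length")
        if n == 0:
            raise ValueError("empty composite series")
        ensure_aligned(*self.layers)
        prev_end = None
        for start, length in zip(self.period_starts, self.period_length_days):
            if length < 1:
                raise ValueError("period length must be >= 1 day")
            if prev_end is not None and start < prev_end:
                raise ValueError("periods must be non-overlapping and ascending")
            prev_end = start + dt.timedelta(days=length)


def _overlap_days(p_start: dt.date, p_days: int, m_start: dt.date, m_end: dt.date) -> int:
    p_end = p_start + dt.timedelta(days=p_days)
    lo = max(p_start, m_start)
    hi = min(p_end, m_end)
    return max((hi - lo).days, 0)


def composite_to_monthly(series: CompositeSeries, year: int | None = None) -> GridStack:
    """Aggregate a composite series to a 12-month stack by day-overlap weighting.

    Month m is the mean of all layers overlapping it, each weighted by its
    number of overlap days; cells masked in a layer are excluded from that
    layer's contribution.  Months (or cells) with no unmasked contribution
    are masked.
    """
    if year is None:
        year = series.period_starts[0].year
    ref = series.layers[0]
    shape = ref.shape
    values = np.zeros((12,) + shape)
    mask = np.ones((12,) + shape, dtype=bool)

    for m in range(1, 13):
        m_start = dt.date(year, m, 1)
        m_end = dt.date(year, m, calendar.monthrange(year, m)[1]) + dt.timedelta(days=1)
        num = np.zeros(shape)
        den = np.zeros(shape)
        for layer, start, length in zip(
            series.layers, series.period_starts, series.period_length_days
        ):
            w = _overlap_days(start, length, m_start, m_end)
            if w == 0:
                continue
            valid = ~layer.mask
            num += np.where(valid, w * layer.values, 0.0)
            den += np.where(valid, float(w), 0.0)
        has_data = den > 0
        values[m - 1][has_data] = num[has_data] / den[has_data]
        mask[m - 1] = ~has_data

    return GridStack(values, ref.georef, mask, units=ref.units)


def gap_fill_time(stack: GridStack) -> GridStack:
    """Fill masked months per cell with a cubic spline along the month axis.

    Observed months are never altered.  Outside the first/last observed
    month the nearest observed value is used (no cubic extrapolation).
    Cells with fewer than two observed months are left masked and counted
    in a log message.
    """
    out = stack.copy()
    months = np.arange(12)
    gap_cells = np.argwhere(stack.mask.any(axis=0))
    n_degenerate = 0
    for r, c in gap_cells:
        valid = ~stack.mask[:, r, c]
        n_valid = int(valid.sum())
        if n_valid < 2:
            n_degenerate += 1
            continue
        x = months[valid]
        y = stack.values[valid, r, c]
        spline = CubicSpline(x, y, bc_type="natural")
        missing = ~valid
        xm = np.clip(months[missing], x[0], x[-1])
        out.values[missing, r, c] = spline(xm)
        out.mask[missing, r, c] = False
    if n_degenerate:
        logger.info("gap_fill_time: %d cells with < 2 observed months left masked", n_degenerate)
    return out


@dataclass
class StationRecord:
    """One meteorological station with 12 monthly mean air temperatures (degC).

    Missing months are NaN.
    """

    station_id: str
    lon: float
    lat: float
    elevation: float
    monthly_mean_temp: list[float] = field(default_factory=lambda: [math.nan] * 12)

    def __post_init__(self) -> None:
        if len(self.monthly_mean_temp) != 12:
            raise ValueError("monthly_mean_temp must have 12 entries")
        if not math.isfinite(self.elevation):
            raise ValueError(f"station {self.station_id}: elevation must be finite")

    def temp(self, month: int) -> float:
        return self.monthly_mean_temp[month - 1]


def lapse_fit(stations: list[StationRecord], month: int) -> tuple[float, float]:
    """Least-squares fit T = a + b*elevation across stations for one month.

    Returns (a, b) with b in degC per metre.  Raises if fewer than three
    stations report the month or all elevations coincide.
    """
    usable = [s for s in stations if math.isfinite(s.temp(month))]
    if len(usable) < 3:
        raise ValueError(f"month {month}: need >= 3 stations with data, have {len(usable)}")
    elev = np.array([s.elevation for s in usable])
    temp = np.array([s.temp(month) for s in usable])
    if np.ptp(elev) == 0:
        raise np.linalg.LinAlgError("all station elevations coincide")
    design = np.column_stack([np.ones_like(elev), elev])
    (a, b), *_ = np.linalg.lstsq(design, temp, rcond=None)
    return float(a), float(b)


def interpolate_station_temperature(
    stations: list[StationRecord],
    dem: Grid,
    month: int,
    smoothing: float = 0.0,
) -> Grid:
    """Grid monthly station temperatures with an elevation-aware scheme.

    Step 1 regresses temperature on station elevation (the lapse-rate fit);
    step 2 interpolates the regression residuals over lon/lat with a
    thin-plate smoothing spline.  The output is a + b*DEM + residual field,
    masked wherever the DEM is masked.  If station elevations are collinear
    the lapse step is skipped and a pure spatial spline is used (warning).
    """
    usable = [s for s in stations if math.isfinite(s.temp(month))]
    if len(usable) < 3:
        raise ValueError(f"month {month}: need >= 3 stations with data, have {len(usable)}")

    temps = np.array([s.temp(month) for s in usable])
    coords = np.array([[s.lon, s.lat] for s in usable])
    try:
        a, b = lapse_fit(usable, month)
        residuals = temps - (a + b * np.array([s.elevation for s in usable]))
        logger.info(
            "interpolate_station_temperature: month %d lapse fit a=%.3f degC, b=%.4f degC/km",
            month, a, b * 1000.0,
        )
    except np.linalg.LinAlgError:
        logger.warning(
            "interpolate_station_temperature: collinear station elevations, "
            "falling back to spatial spline only"
        )
        a, b = float(np.mean(temps)), 0.0
        residuals = temps - a
    if not (math.isfinite(a) and math.isfinite(b)):
        raise ValueError("lapse-rate fit produced non-finite coefficients")

    lon, lat = dem.georef.cell_centers(dem.shape)
    targets = np.column_stack([lon.ravel(), lat.ravel()])
    if np.ptp(residuals) == 0:
        resid_field = np.full(dem.shape, residuals[0])
    else:
        try:
            rbf = RBFInterpolator(
                coords, residuals, kernel="thin_plate_spline", smoothing=smoothing
            )
            resid_field = rbf(targets).reshape(dem.shape)
        except np.linalg.LinAlgError:
            logger.warning(
                "interpolate_station_temperature: singular spline system, "
                "using mean residual"
            )
            resid_field = np.full(dem.shape, float(np.mean(residuals)))

    values = a + b * dem.values + resid_field
    return Grid(values, dem.georef, dem.mask.copy(), units="degC")


def interpolate_station_temperature_stack(
    stations: list[StationRecord], dem: Grid, smoothing: float = 0.0
) -> GridStack:
    """All 12 monthly temperature grids as one stack."""
    grids = [
        interpolate_station_temperature(stations, dem, m, smoothing=smoothing)
        for m in range(1, 13)
    ]
    values = np.stack([g.values for g in grids])
    mask = np.stack([g.mask for g in grids])
    return GridStack(values, dem.georef, mask, units="degC")
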