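"""Georeferenced grid containers.

A :class:`Grid` is a single 2-D raster layer; a :class:`GridStack` is a
12-layer monthly stack sharing one georeference.  Both carry an explicit
boolean nodata mask (True = missing) instead of sentinel values, so masks
survive arithmetic and union cleanly along a processing chain.

The georeference is a north-up affine in a geographic CRS: row 0 is the
northernmost row, pixel sizes are positive degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_MONTHS = 12


class AlignmentError(ValueError):
    """Two grids that must share shape and georeference do not."""


@dataclass(frozen=True)
class GeoRef:
    """North-up affine georeference in a geographic CRS.

    Parameters
    ----------
    west, north : float
        Coordinates of the outer corner of pixel (0, 0), degrees.
    dx, dy : float
        Pixel size in degrees (both positive; rows run north to south).
    crs : str
        CRS identifier; only geographic CRSs are supported.
    """

    west: float
    north: float
    dx: float
    dy: float
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("pixel sizes must be positive")

    @property
    def is_geographic(self) -> bool:
        return self.crs.upper() in ("EPSG:4326", "WGS84", "CRS:84")

    def cell_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return (lon, lat) arrays of cell-center coordinates for ``shape``."""
        rows, cols = shape
        lon = self.west + (np.arange(cols) + 0.5) * self.dx
        lat = self.north - (np.arange(rows) + 0.5) * self.dy
        return np.meshgrid(lon, lat)

    def rowcol(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/column of the pixel containing (lon, lat)."""
        col = int(np.floor((lon - self.west) / self.dx))
        row = int(np.floor((self.north - lat) / self.dy))
        return row, col

    def approx_equal(self, other: "GeoRef", tol: float = 1e-9) -> bool:
        return (
            self.crs.upper() == other.crs.upper()
            and abs(self.west - other.west) <= tol
            and abs(self.north - other.north) <= tol
            and abs(self.dx - other.dx) <= tol
            and abs(self.dy - other.dy) <= tol
        )


def _as_mask(mask, shape) -> np.ndarray:
    if mask is None:
        return np.zeros(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} != values shape {shape}")
    return mask


@dataclass
class Grid:
    """One 2-D raster layer with nodata mask, georeference and units."""

    values: np.ndarray
    georef: GeoRef
    mask: np.ndarray | None = None
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        self.mask = _as_mask(self.mask, self.values.shape)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def filled(self, fill=np.nan) -> np.ndarray:
        out = self.values.copy()
        out[self.mask] = fill
        return out

    def copy(self) -> "Grid":
        return Grid(self.values.copy(), self.georef, self.mask.copy(), self.units)


@dataclass
class GridStack:
    """A 12-month stack of aligned raster layers.

    ``values`` has shape (12, rows, cols); ``mask`` is boolean of the same
    shape with True marking nodata.  All layers share one georeference.
    """

    values: np.ndarray
    georef: GeoRef
    mask: np.ndarray | None = None
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != N_MONTHS:
            raise ValueError(
                f"GridStack values must have shape (12, rows, cols), got {self.values.shape}"
            )
        self.mask = _as_mask(self.mask, self.values.shape)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def month(self, m: int) -> Grid:
        """Layer for calendar month ``m`` (1-based)."""
        if not 1 <= m <= N_MONTHS:
            raise ValueError("month must be in 1..12")
        return Grid(self.values[m - 1], self.georef, self.mask[m - 1], self.units)

    def filled(self, fill=np.nan) -> np.ndarray:
        out = self.values.copy()
        out[self.mask] = fill
        return out

    def copy(self) -> "GridStack":
        return GridStack(self.values.copy(), self.georef, self.mask.copy(), self.units)

    @classmethod
    def full_like(cls, other: "GridStack", fill: float = 0.0, units: str = "") -> "GridStack":
        return cls(
            np.full_like(other.values, fill),
            other.georef,
            other.mask.copy(),
            units,
        )


def ensure_aligned(*rasters, names: list[str] | None = None) -> None:
    """Raise :class:`AlignmentError` unless all grids/stacks share shape and georef.

    ``names`` lets the error name the offending layer.
    """
    if not rasters:
        return
    ref = rasters[0]
    ref_name = names[0] if names else "input 0"
    for i, r in enumerate(rasters[1:], start=1):
        name = names[i] if names else f"input {i}"
        if r.shape != ref.shape:
            raise AlignmentError(
                f"{name} shape {r.shape} does not match {ref_name} shape {ref.shape}"
            )
        if not r.georef.approx_equal(ref.georef):
            raise AlignmentError(f"{name} georeference does not match {ref_name}")
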