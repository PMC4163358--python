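"""Readers and writers for rasters, station/point tables and run configs.

Rasters travel as ESRI ASCII grids (one ``.asc`` file per layer, plain
text, ``nodata_value`` honored) with a JSON sidecar per raster carrying
the full georeference (the ``.asc`` header only allows square cells), CRS,
units and the month index for stacks.  A monthly stack is a set of files
``<name>_m01.asc`` .. ``<name>_m12.asc`` next to ``<name>.json``.

Tables are CSV: stations as (station_id, lon, lat, elevation_m, t01..t12),
in-situ points as (point_id, lon, lat, date, grassland_type,
dry_yield_g_m2).  Run configuration is YAML.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grids import GeoRef, Grid, GridStack, N_MONTHS
from .params import DEFAULT_ELEVATION_BREAKS, ModelParams
from .preprocessing import StationRecord
from .validation import InSituPoint, ValidationRow
from .summaries import PartitionStats

NODATA = -9999.0


# ---------------------------------------------------------------- rasters

def _write_asc(path: Path, values: np.ndarray, mask: np.ndarray, georef: GeoRef) -> None:
    rows, cols = values.shape
    south = georef.north - rows * georef.dy
    out = np.where(mask, NODATA, values)
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {georef.west!r}\n"
        f"yllcorner {south!r}\n"
        f"cellsize {georef.dx!r}\n"
        f"nodata_value {NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.17g")


def _read_asc(path: Path) -> tuple[np.ndarray, np.ndarray, dict]:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    nodata = header.get("nodata_value", NODATA)
    mask = values == nodata
    return values, mask, header


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _georef_to_dict(georef: GeoRef) -> dict:
    return {
        "west": georef.west, "north": georef.north,
        "dx": georef.dx, "dy": georef.dy, "crs": georef.crs,
    }


def _georef_from_dict(d: dict) -> GeoRef:
    return GeoRef(d["west"], d["north"], d["dx"], d["dy"], d.get("crs", "EPSG:4326"))


def write_grid(grid: Grid, path: str | Path) -> None:
    """Write one layer as <path>.asc plus a JSON georeference sidecar."""
    path = Path(path).with_suffix(".asc")
    _write_asc(path, grid.values, grid.mask, grid.georef)
    meta = {"georef": _georef_to_dict(grid.georef), "units": grid.units, "bands": 1}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_grid(path: str | Path) -> Grid:
    """Read one layer; the JSON sidecar is required (carries CRS and dy)."""
    path = Path(path).with_suffix(".asc")
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(f"{path}: georeference sidecar {side.name} missing (no CRS)")
    meta = json.loads(side.read_text())
    values, mask, _ = _read_asc(path)
    return Grid(values, _georef_from_dict(meta["georef"]), mask, meta.get("units", ""))


def write_raster_stack(stack: GridStack, directory: str | Path, name: str) -> None:
    """Write a 12-month stack as <name>_m01.asc .. <name>_m12.asc + <name>.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for m in range(1, N_MONTHS + 1):
        _write_asc(directory / f"{name}_m{m:02d}.asc",
                   stack.values[m - 1], stack.mask[m - 1], stack.georef)
    meta = {
        "georef": _georef_to_dict(stack.georef),
        "units": stack.units,
        "bands": N_MONTHS,
        "band_files": [f"{name}_m{m:02d}.asc" for m in range(1, N_MONTHS + 1)],
    }
    (directory / f"{name}.json").write_text(json.dumps(meta, indent=1))


def read_raster_stack(directory: str | Path, name: str) -> GridStack:
    """Read a 12-month stack written by :func:`write_raster_stack`.

    Raises if the index lists a band count other than 12 or a band file is
    missing, naming the offending file.
    """
    directory = Path(directory)
    index = directory / f"{name}.json"
    if not index.exists():
        raise FileNotFoundError(f"stack index {index} not found")
    meta = json.loads(index.read_text())
    band_files = meta.get("band_files", [])
    if meta.get("bands") != N_MONTHS or len(band_files) != N_MONTHS:
        raise ValueError(
            f"{index}: a monthly stack needs {N_MONTHS} bands, found {len(band_files)}"
        )
    georef = _georef_from_dict(meta["georef"])
    layers, masks = [], []
    for fname in band_files:
        fpath = directory / fname
        if not fpath.exists():
            raise FileNotFoundError(f"stack band {fpath} missing")
        values, mask, _ = _read_asc(fpath)
        layers.append(values)
        masks.append(mask)
    return GridStack(np.stack(layers), georef, np.stack(masks), meta.get("units", ""))


# ----------------------------------------------------------------- tables

def write_stations_csv(stations: list[StationRecord], path: str | Path) -> None:
    rows = []
    for s in stations:
        row = {"station_id": s.station_id, "lon": s.lon, "lat": s.lat,
               "elevation_m": s.elevation}
        row.update({f"t{m:02d}": s.monthly_mean_temp[m - 1] for m in range(1, 13)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_stations_csv(path: str | Path) -> list[StationRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    cols = ["station_id", "lon", "lat", "elevation_m"] + [f"t{m:02d}" for m in range(1, 13)]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing station columns {missing}")
    return [
        StationRecord(
            station_id=str(r["station_id"]), lon=float(r["lon"]), lat=float(r["lat"]),
            elevation=float(r["elevation_m"]),
            monthly_mean_temp=[float(r[f"t{m:02d}"]) for m in range(1, 13)],
        )
        for _, r in df.iterrows()
    ]


def write_insitu_csv(points: list[InSituPoint], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "point_id": p.point_id, "lon": p.lon, "lat": p.lat,
                "date": p.date.isoformat(), "grassland_type": p.grassland_type,
                "dry_yield_g_m2": p.dry_yield,
            }
            for p in points
        ]
    ).to_csv(path, index=False, float_format="%.17g")


def read_insitu_csv(path: str | Path) -> list[InSituPoint]:
    df = pd.read_csv(path, float_precision="round_trip")
    cols = ["point_id", "lon", "lat", "date", "grassland_type", "dry_yield_g_m2"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing in-situ columns {missing}")
    return [
        InSituPoint(
            point_id=str(r["point_id"]), lon=float(r["lon"]), lat=float(r["lat"]),
            date=dt.date.fromisoformat(str(r["date"])),
            grassland_type=str(r["grassland_type"]),
            dry_yield=float(r["dry_yield_g_m2"]),
        )
        for _, r in df.iterrows()
    ]


def write_validation_report(rows: list[ValidationRow], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "grassland_type": r.grassland_type,
                "validation_points": r.n_points,
                "error_pct": r.error_pct,
                "precision_pct": r.precision_pct,
            }
            for r in rows
        ]
    ).to_csv(path, index=False)


def write_partition_table(rows: list[PartitionStats], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "class": r.class_label,
                "area_km2": r.area_km2,
                "area_pct": r.area_pct,
                "mean": r.mean_value,
                "max": r.max_value,
                "total": r.total,
                "total_pct": r.total_pct,
            }
            for r in rows
        ]
    ).to_csv(path, index=False)


# ----------------------------------------------------------------- config

_STACK_KEYS = ("sol", "fpar", "temperature", "lst", "precipitable_water")


@dataclass
class RunConfig:
    """Paths and options for one pipeline run (all raster paths are
    (directory, stack-name) implied: value is the stack name inside
    ``input_dir``)."""

    input_dir: str = "."
    output_dir: str = "out"
    sol: str = "sol"
    fpar: str = "fpar"
    temperature: str = "temperature"
    lst: str = "lst"
    precipitable_water: str = "precipitable_water"
    dem: str = "dem"
    grassland_types: str = "grassland_types"
    regions: str = "regions"
    stations_csv: str | None = None
    insitu_csv: str | None = None
    type_legend: dict = dc_field(default_factory=dict)
    region_legend: dict = dc_field(default_factory=dict)
    params: dict = dc_field(default_factory=dict)
    elevation_breaks: list = dc_field(default_factory=lambda: list(DEFAULT_ELEVATION_BREAKS))
    validation_period: str | int = "annual"
    area_weighted_mean: bool = True

    def model_params(self) -> ModelParams:
        return ModelParams().with_overrides(self.params)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run config; unknown keys are rejected, defaults applied."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    valid = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - valid)
    if unknown:
        raise KeyError(f"{path}: unknown config key(s) {unknown}; valid keys: {sorted(valid)}")
    cfg = RunConfig(**raw)
    cfg.model_params()  # reject unknown parameter overrides early
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    data = {k: getattr(cfg, k) for k in RunConfig.__dataclass_fields__}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
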