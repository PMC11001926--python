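"""Gridded daily weather: container, validation, I/O, and astronomical helpers.

The central object is :class:`WeatherGrid`, a long-format table of daily
meteorology (tmin, tmax, tavg, precip, pet, radiation) for a set of grid
cells sharing one contiguous daily calendar, plus per-cell coordinates.
It emulates the structure of an 8-km reanalysis extract: one row per
cell-day, physical units normalized on entry (temperatures in °C,
precipitation and PET in mm/day, radiation as a daily-mean W/m²).

Also provided: astronomical day length (needed by the photoperiod response
of long-day cereals) and a Hargreaves–Samani PET fallback for sources that
do not supply potential evapotranspiration.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "WeatherGrid",
    "WeatherFormatError",
    "WeatherValidationError",
    "VARIABLES",
    "load_weather",
    "daylength",
    "pet_hargreaves",
    "extraterrestrial_radiation",
]

#: canonical per-cell-day variables, in canonical column order
VARIABLES = ("tmin", "tmax", "tavg", "precip", "pet", "radiation")

#: conversion for radiation supplied as MJ m-2 day-1 into daily-mean W m-2
MJ_PER_DAY_TO_WM2 = 1.0 / 0.0864


class WeatherFormatError(ValueError):
    """A required variable is missing and cannot be derived."""


class WeatherValidationError(ValueError):
    """Physical or calendar invariants are violated."""


@dataclasses.dataclass
class WeatherGrid:
    """Daily weather for a set of cells on one shared contiguous calendar.

    Parameters
    ----------
    frame
        Long table indexed by a (cell_id, date) MultiIndex with the columns
        in :data:`VARIABLES`. Dates are daily ``pd.Timestamp`` (proleptic
        Gregorian, real leap years).
    cells
        One row per cell, indexed by cell_id, with at least ``lat`` and
        ``lon`` (degrees); ``elev`` (m) optional.
    """

    frame: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.frame = self.frame.sort_index()
        self.validate()

    # -- basic accessors ---------------------------------------------------

    @property
    def cell_ids(self) -> list:
        return list(self.cells.index)

    @property
    def calendar(self) -> pd.DatetimeIndex:
        return self.frame.index.get_level_values("date").unique().sort_values()

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell(self, cell_id) -> pd.DataFrame:
        """Daily series for one cell, indexed by date."""
        return self.frame.xs(cell_id, level="cell_id")

    def latitude(self, cell_id) -> float:
        return float(self.cells.loc[cell_id, "lat"])

    def subset(self, cell_ids: Iterable) -> "WeatherGrid":
        ids = list(cell_ids)
        return WeatherGrid(
            frame=self.frame.loc[self.frame.index.get_level_values("cell_id").isin(ids)],
            cells=self.cells.loc[ids],
        )

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        f = self.frame
        missing = [v for v in VARIABLES if v not in f.columns]
        if missing:
            raise WeatherFormatError(f"missing weather variables: {missing}")
        if not {"lat", "lon"} <= set(self.cells.columns):
            raise WeatherFormatError("cell table needs 'lat' and 'lon' columns")
        lat = self.cells["lat"]
        if (lat.abs() > 90).any():
            bad = self.cells.index[lat.abs() > 90].tolist()
            raise WeatherValidationError(f"latitude outside [-90, 90] for cells {bad}")

        bad = f.index[f["tmin"] > f["tmax"] + 1e-9]
        if len(bad):
            raise WeatherValidationError(f"tmin > tmax at cell-days {bad[:5].tolist()}")
        bad = f.index[(f["tavg"] < f["tmin"] - 1e-9) | (f["tavg"] > f["tmax"] + 1e-9)]
        if len(bad):
            raise WeatherValidationError(
                f"tavg outside [tmin, tmax] at cell-days {bad[:5].tolist()}"
            )
        for var in ("precip", "pet", "radiation"):
            if (f[var] < -1e-9).any():
                first = f.index[f[var] < -1e-9][0]
                raise WeatherValidationError(f"negative {var} at {first}")
        if f[list(VARIABLES)].isna().any().any():
            raise WeatherValidationError("NaN values in weather variables")

        cal = self.calendar
        full = pd.date_range(cal[0], cal[-1], freq="D")
        if len(cal) != len(full):
            gap = full.difference(cal)[0]
            raise WeatherValidationError(f"calendar gap: first missing date {gap.date()}")
        counts = f.groupby(level="cell_id").size()
        if counts.nunique() > 1 or (counts != len(cal)).any():
            raise WeatherValidationError("cells do not share the same calendar")

    # -- I/O -----------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Long CSV, one row per cell-day: cell_id, date (ISO), lat, lon, variables."""
        out = self.frame.reset_index()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        meta = self.cells[["lat", "lon"]].reset_index().rename(columns={"index": "cell_id"})
        if "cell_id" not in meta.columns:
            meta.insert(0, "cell_id", self.cells.index)
        out = out.merge(meta, on="cell_id")
        cols = ["cell_id", "date", "lat", "lon", *VARIABLES]
        out[cols].to_csv(path, index=False, float_format="%.6f")

    def to_netcdf(self, path) -> None:
        """CF-style NetCDF with dimensions (cell, time)."""
        cal = self.calendar
        ids = self.cell_ids
        data = {
            var: (("cell", "time"),
                  self.frame[var].unstack(level="date").reindex(index=ids, columns=cal).values)
            for var in VARIABLES
        }
        ds = xr.Dataset(
            data,
            coords={
                "cell": np.arange(len(ids)),
                "cell_id": ("cell", np.asarray(ids, dtype="U32")),
                "time": cal,
                "lat": ("cell", self.cells["lat"].values),
                "lon": ("cell", self.cells["lon"].values),
            },
        )
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, cells: pd.DataFrame) -> "WeatherGrid":
        """Build from a long frame, deriving tavg = (tmin+tmax)/2 when absent."""
        frame = frame.copy()
        if "tavg" not in frame.columns:
            if {"tmin", "tmax"} <= set(frame.columns):
                frame["tavg"] = 0.5 * (frame["tmin"] + frame["tmax"])
            else:
                raise WeatherFormatError("missing weather variables: ['tavg']")
        return cls(frame=frame, cells=cells)


def _load_csv(path) -> WeatherGrid:
    df = pd.read_csv(path)
    required = {"cell_id", "date", "lat", "lon"}
    if not required <= set(df.columns):
        raise WeatherFormatError(f"CSV missing columns: {sorted(required - set(df.columns))}")
    df["date"] = pd.to_datetime(df["date"])
    cells = df.groupby("cell_id")[["lat", "lon"]].first()
    keep = [c for c in VARIABLES if c in df.columns]
    frame = df.set_index(["cell_id", "date"])[keep]
    return WeatherGrid.from_frame(frame, cells)


def _load_netcdf(path, name_map: Mapping[str, str] | None = None) -> WeatherGrid:
    ds = xr.open_dataset(path, engine="scipy")
    if name_map:
        ds = ds.rename({v: k for k, v in name_map.items() if v in ds})
    if "cell_id" in ds:
        ids = [str(v) for v in np.asarray(ds["cell_id"].values)]
    else:
        ids = [f"c{i}" for i in range(ds.sizes["cell"])]
    cal = pd.DatetimeIndex(ds["time"].values)
    idx = pd.MultiIndex.from_product([ids, cal], names=["cell_id", "date"])
    cols = {}
    for var in VARIABLES:
        if var in ds:
            cols[var] = np.asarray(ds[var].values, dtype=float).reshape(-1)
    frame = pd.DataFrame(cols, index=idx)
    cells = pd.DataFrame(
        {"lat": np.asarray(ds["lat"].values, float), "lon": np.asarray(ds["lon"].values, float)},
        index=pd.Index(ids, name="cell_id"),
    )
    ds.close()
    return WeatherGrid.from_frame(frame, cells)


def load_weather(path, format: str | None = None,
                 name_map: Mapping[str, str] | None = None) -> WeatherGrid:
    """Read a weather grid from long-format CSV or CF-style NetCDF.

    ``format`` is inferred from the suffix when omitted. ``name_map`` maps
    canonical variable names to the names used in a NetCDF source.
    Missing tavg is derived as (tmin+tmax)/2.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("netcdf" if path.suffix in {".nc", ".nc4", ".cdf"} else "csv")
    if fmt == "netcdf":
        return _load_netcdf(path, name_map)
    if fmt == "csv":
        return _load_csv(path)
    raise ValueError(f"unknown weather format {fmt!r}")


# ---------------------------------------------------------------------------
# astronomy


def _solar_declination(day_of_year: np.ndarray | int) -> np.ndarray:
    """Solar declination (radians), FAO-56 eq. 24."""
    doy = np.asarray(day_of_year, dtype=float)
    return 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)


def daylength(latitude: float, day_of_year) -> np.ndarray | float:
    """Astronomical day length in hours (sun centre at −0.833° elevation).

    Vectorized over ``day_of_year``. Polar day/night saturate at 24/0 h.
    """
    if np.any(np.abs(latitude) > 90):
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    phi = np.deg2rad(latitude)
    delta = _solar_declination(day_of_year)
    h0 = np.deg2rad(-0.833)
    cos_omega = (np.sin(h0) - np.sin(phi) * np.sin(delta)) / (np.cos(phi) * np.cos(delta))
    cos_omega = np.clip(cos_omega, -1.0, 1.0)
    hours = 24.0 / np.pi * np.arccos(cos_omega)
    return float(hours) if np.isscalar(day_of_year) else hours


def extraterrestrial_radiation(latitude: float, day_of_year) -> np.ndarray | float:
    """Top-of-atmosphere daily radiation Ra in MJ m-2 day-1 (FAO-56 eq. 21)."""
    phi = np.deg2rad(latitude)
    doy = np.asarray(day_of_year, dtype=float)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    delta = _solar_declination(doy)
    cos_ws = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    ws = np.arccos(cos_ws)
    gsc = 0.0820  # MJ m-2 min-1
    ra = (24.0 * 60.0 / np.pi) * gsc * dr * (
        ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws)
    )
    ra = np.maximum(ra, 0.0)
    return float(ra) if np.isscalar(day_of_year) else ra


def pet_hargreaves(tmin, tmax, latitude: float, day_of_year) -> np.ndarray | float:
    """Hargreaves–Samani reference PET in mm/day.

    ET0 = 0.0023 · (Ra/λ) · (Tmean + 17.8) · √(Tmax − Tmin), λ = 2.45 MJ/kg.
    Clamped at zero; used as a fallback when a source supplies no PET.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmin > tmax + 1e-9):
        raise ValueError("tmin > tmax in Hargreaves PET input")
    ra = extraterrestrial_radiation(latitude, day_of_year)
    tmean = 0.5 * (tmin + tmax)
    pet = 0.0023 * (np.asarray(ra) / 2.45) * (tmean + 17.8) * np.sqrt(
        np.maximum(tmax - tmin, 0.0)
    )
    pet = np.maximum(pet, 0.0)
    return float(pet) if pet.ndim == 0 else pet
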