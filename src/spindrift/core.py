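"""Shared gridded and time-series containers.

Coordinates are local Cartesian metres with x pointing east and y north.
The synthetic coast is laid out with the shoreline running alongshore
(north--south), ocean at negative x, land at positive x, but nothing in
the containers assumes that orientation.

Wind direction is everywhere the meteorological convention: the compass
direction the wind blows FROM, degrees clockwise from north.  This is
the dominant silent-failure mode in source attribution, so conversions
to/from Cartesian components live here and nowhere else.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _as_times(times) -> np.ndarray:
    t = np.asarray(times, dtype="datetime64[s]")
    if t.ndim != 1:
        raise ValueError("times must be one-dimensional")
    return t


def times_to_seconds(times: np.ndarray) -> np.ndarray:
    """Epoch seconds as float, for interpolation."""
    return np.asarray(times, dtype="datetime64[s]").astype("int64").astype(float)


# ---------------------------------------------------------------------------
# time series


@dataclass
class WaterLevelSeries:
    """Water level (tide) above datum, metres."""

    times: np.ndarray
    eta_m: np.ndarray

    def __post_init__(self) -> None:
        self.times = _as_times(self.times)
        self.eta_m = np.asarray(self.eta_m, dtype=float)
        if self.times.shape != self.eta_m.shape:
            raise ValueError("times and eta_m must have the same length")
        if len(self.times) and np.any(np.diff(self.times).astype(int) <= 0):
            raise ValueError("times must be strictly increasing")

    def at(self, target_times) -> np.ndarray:
        """Linear interpolation of water level at the target times."""
        tt = times_to_seconds(_as_times(np.atleast_1d(target_times)))
        ts = times_to_seconds(self.times)
        if tt.min() < ts[0] or tt.max() > ts[-1]:
            raise ValueError("target times outside the water-level record")
        return np.interp(tt, ts, self.eta_m)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "eta_m": self.eta_m})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WaterLevelSeries":
        df = pd.read_csv(path, parse_dates=["time"])
        return cls(df["time"].to_numpy(), df["eta_m"].to_numpy())


@dataclass
class WindSeries:
    """Wind speed (m/s) and meteorological FROM-direction (deg) at a station."""

    times: np.ndarray
    speed_ms: np.ndarray
    dir_deg_from: np.ndarray

    def __post_init__(self) -> None:
        self.times = _as_times(self.times)
        self.speed_ms = np.asarray(self.speed_ms, dtype=float)
        self.dir_deg_from = wrap_direction(self.dir_deg_from)
        n = len(self.times)
        if len(self.speed_ms) != n or len(self.dir_deg_from) != n:
            raise ValueError("times, speed and direction must have equal length")
        if n and np.any(np.diff(self.times).astype(int) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.speed_ms < 0):
            raise ValueError("wind speed must be non-negative")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "speed_ms": self.speed_ms, "dir_deg_from": self.dir_deg_from}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WindSeries":
        df = pd.read_csv(path, parse_dates=["time"])
        return cls(
            df["time"].to_numpy(), df["speed_ms"].to_numpy(), df["dir_deg_from"].to_numpy()
        )


def wrap_direction(deg):
    """Wrap degrees into [0, 360); rounding can make np.mod return 360."""
    d = np.mod(np.asarray(deg, dtype=float), 360.0)
    return np.where(d >= 360.0, d - 360.0, d)


def wind_to_uv(speed_ms, dir_deg_from):
    """Meteorological (speed, FROM-direction) -> Cartesian (u east, v north).

    A wind FROM the west (270 deg) blows TOWARD the east: u > 0.
    """
    theta = np.deg2rad(np.asarray(dir_deg_from, dtype=float))
    s = np.asarray(speed_ms, dtype=float)
    u = -s * np.sin(theta)
    v = -s * np.cos(theta)
    return u, v


def uv_to_wind(u, v):
    """Cartesian components -> meteorological (speed, FROM-direction)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    speed = np.hypot(u, v)
    direction = wrap_direction(np.rad2deg(np.arctan2(-u, -v)))
    return speed, direction


# ---------------------------------------------------------------------------
# gridded fields


def _grid_header(meta: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def _read_grid_ascii(path):
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    data = np.loadtxt(lines[body_start:], dtype=float, ndmin=2)
    return meta, data


@dataclass
class Terrain:
    """Elevation above datum (m) sampled at grid nodes.

    ``origin`` is the (x, y) coordinate of node [0, 0]; node [iy, ix] sits
    at origin + (ix, iy) * cell_size.  Array layout is (ny, nx).
    """

    elevation: np.ndarray
    origin: tuple
    cell_size: float

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.ndim != 2:
            raise ValueError("elevation must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def x(self) -> np.ndarray:
        return self.origin[0] + self.cell_size * np.arange(self.elevation.shape[1])

    @property
    def y(self) -> np.ndarray:
        return self.origin[1] + self.cell_size * np.arange(self.elevation.shape[0])

    def to_ascii(self, path) -> None:
        meta = {
            "origin_x": self.origin[0],
            "origin_y": self.origin[1],
            "cell_size": self.cell_size,
        }
        with open(path, "w") as fh:
            fh.write(_grid_header(meta))
            np.savetxt(fh, self.elevation, fmt="%.4f")

    @classmethod
    def from_ascii(cls, path) -> "Terrain":
        meta, data = _read_grid_ascii(path)
        return cls(
            data,
            (float(meta["origin_x"]), float(meta["origin_y"])),
            float(meta["cell_size"]),
        )


@dataclass
class DyeMap:
    """One time-stamped sea-surface tracer concentration raster (ppb).

    ``origin`` is the (x, y) of the grid corner; the centre of cell
    [iy, ix] sits at origin + (ix + 0.5, iy + 0.5) * cell_size.  Missing
    observations are NaN.
    """

    time: np.datetime64
    conc_ppb: np.ndarray
    origin: tuple
    cell_size: float = 2.0

    def __post_init__(self) -> None:
        self.time = np.datetime64(self.time, "s")
        self.conc_ppb = np.asarray(self.conc_ppb, dtype=float)
        if self.conc_ppb.ndim != 2:
            raise ValueError("conc_ppb must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if np.any(self.conc_ppb[np.isfinite(self.conc_ppb)] < 0):
            raise ValueError("concentrations must be non-negative")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin[0] + self.cell_size * (np.arange(self.conc_ppb.shape[1]) + 0.5)

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin[1] + self.cell_size * (np.arange(self.conc_ppb.shape[0]) + 0.5)

    def integrated_mass(self) -> float:
        """Grid-integrated tracer content, ppb * m^2."""
        return float(np.nansum(self.conc_ppb) * self.cell_size**2)

    def to_ascii(self, path) -> None:
        meta = {
            "time": np.datetime_as_string(self.time, unit="s"),
            "origin_x": self.origin[0],
            "origin_y": self.origin[1],
            "cell_size": self.cell_size,
        }
        with open(path, "w") as fh:
            fh.write(_grid_header(meta))
            np.savetxt(fh, self.conc_ppb, fmt="%.6g")

    @classmethod
    def from_ascii(cls, path) -> "DyeMap":
        meta, data = _read_grid_ascii(path)
        return cls(
            np.datetime64(meta["time"]),
            data,
            (float(meta["origin_x"]), float(meta["origin_y"])),
            float(meta["cell_size"]),
        )
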