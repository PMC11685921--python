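"""Gridded environmental fields (SST, currents, wind) and σ-SST statistics.

Fields live on regular lat/lon/daily-time grids.  Interpolation is bilinear
in space and linear in time; an optional validity mask marks land cells,
and queries whose enclosing cell touches masked nodes fall back to the
nearest valid corner node (within one cell) or raise.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "GridField",
    "EnvStats",
    "DomainError",
    "InsufficientDataError",
    "interpolate_field",
    "trajectory_env_stats",
    "static_point_stats",
    "read_field_netcdf",
    "write_field_netcdf",
    "read_field_csv",
    "write_field_csv",
]


class DomainError(ValueError):
    """Query outside the grid bounds (message names the offending axis)."""


class InsufficientDataError(ValueError):
    """Fewer in-bounds samples than the statistic requires."""


@dataclasses.dataclass
class GridField:
    """A scalar or vector-component field on a regular (time, lat, lon) grid.

    Parameters
    ----------
    lats, lons : 1-D arrays, strictly ascending, degrees.
    times : 1-D array, strictly ascending, days since an arbitrary epoch.
    values : array of shape (len(times), len(lats), len(lons)).
    kind : "scalar" | "vector_u" | "vector_v".
    mask : optional (lat, lon) boolean array, True where the cell is valid
        water.  None means everywhere valid.
    """

    lats: np.ndarray
    lons: np.ndarray
    times: np.ndarray
    values: np.ndarray
    kind: str = "scalar"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        for name, ax in (("lats", self.lats), ("lons", self.lons), ("times", self.times)):
            if ax.ndim != 1 or len(ax) < 1:
                raise ValueError(f"{name} must be a non-empty 1-D array")
            if len(ax) > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError(f"{name} must be strictly ascending")
        expected = (len(self.times), len(self.lats), len(self.lons))
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} != (time, lat, lon) {expected}"
            )
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (len(self.lats), len(self.lons)):
                raise ValueError("mask shape must be (lat, lon)")
            if np.any(~np.isfinite(self.values[:, self.mask])):
                raise ValueError("NaN inside declared valid mask")

    @property
    def bounds(self) -> dict:
        return {
            "lat": (self.lats[0], self.lats[-1]),
            "lon": (self.lons[0], self.lons[-1]),
            "time": (self.times[0], self.times[-1]),
        }

    def covers(self, lat: float, lon: float, time: float) -> bool:
        b = self.bounds
        return (
            b["lat"][0] <= lat <= b["lat"][1]
            and b["lon"][0] <= lon <= b["lon"][1]
            and b["time"][0] <= time <= b["time"][1]
        )


@dataclasses.dataclass
class EnvStats:
    """Mean and sample standard deviation of SST over a set of samples."""

    mean_sst: float
    sigma_sst: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples >= 2 and self.sigma_sst < 0:
            raise ValueError("sigma_sst must be >= 0")


def _bracket(axis: np.ndarray, x: float, name: str) -> tuple[int, int, float]:
    """Indices (i0, i1) with axis[i0] <= x <= axis[i1] and the weight on i1."""
    if x < axis[0] or x > axis[-1]:
        raise DomainError(
            f"query {name}={x} outside grid bounds [{axis[0]}, {axis[-1]}] on axis '{name}'"
        )
    if len(axis) == 1:
        return 0, 0, 0.0
    i1 = int(np.searchsorted(axis, x, side="left"))
    if i1 == 0:
        return 0, 0, 0.0
    i0 = i1 - 1
    if i1 >= len(axis):  # x == axis[-1]
        return len(axis) - 1, len(axis) - 1, 0.0
    w = (x - axis[i0]) / (axis[i1] - axis[i0])
    return i0, i1, float(w)


def _spatial_value(field: GridField, ti: int, lat: float, lon: float) -> float:
    """Bilinear value at one time slice, applying the land-mask fallback."""
    j0, j1, wy = _bracket(field.lats, lat, "lat")
    k0, k1, wx = _bracket(field.lons, lon, "lon")
    sl = field.values[ti]
    corners = [(j0, k0), (j0, k1), (j1, k0), (j1, k1)]
    if field.mask is not None:
        valid = [field.mask[j, k] for j, k in corners]
        if not all(valid):
            # nearest valid corner within the enclosing cell, else error
            best, best_d = None, np.inf
            for (j, k), ok in zip(corners, valid):
                if not ok:
                    continue
                d = (field.lats[j] - lat) ** 2 + (field.lons[k] - lon) ** 2
                if d < best_d:
                    best, best_d = (j, k), d
            if best is None:
                raise DomainError(
                    f"query (lat={lat}, lon={lon}) lies in a fully masked cell"
                )
            return float(sl[best])
    v00 = sl[j0, k0]
    v01 = sl[j0, k1]
    v10 = sl[j1, k0]
    v11 = sl[j1, k1]
    return float(
        (1 - wy) * ((1 - wx) * v00 + wx * v01) + wy * ((1 - wx) * v10 + wx * v11)
    )


def interpolate_field(field: GridField, lat: float, lon: float, time: float) -> float:
    """Bilinear-in-space, linear-in-time interpolation; exact at grid nodes."""
    t0, t1, wt = _bracket(field.times, time, "time")
    v0 = _spatial_value(field, t0, lat, lon)
    if t1 == t0 or wt == 0.0:
        return v0
    v1 = _spatial_value(field, t1, lat, lon)
    return (1 - wt) * v0 + wt * v1


def _stats_from_samples(samples: Sequence[float]) -> EnvStats:
    arr = np.asarray(samples, dtype=float)
    if len(arr) < 2:
        raise InsufficientDataError(
            f"need >= 2 in-bounds samples for sigma_sst, got {len(arr)}"
        )
    return EnvStats(
        mean_sst=float(arr.mean()),
        sigma_sst=float(arr.std(ddof=1)),
        n_samples=int(len(arr)),
    )


def trajectory_env_stats(traj, sst: GridField) -> EnvStats:
    """Mean / sample sd of interpolated SST over a trajectory's states.

    ``traj`` only needs ``times``, ``lats``, ``lons`` attributes (arrays of
    equal length).  Out-of-bounds states are skipped; at least two in-bounds
    states are required.
    """
    samples = []
    for t, la, lo in zip(traj.times, traj.lats, traj.lons):
        if sst.covers(la, lo, t):
            samples.append(interpolate_field(sst, la, lo, t))
    return _stats_from_samples(samples)


def static_point_stats(
    sst: GridField,
    lat: float,
    lon: float,
    end_time: float,
    window_days: int = 11,
) -> EnvStats:
    """EnvStats at a fixed point over the ``window_days`` ending at ``end_time``.

    The window is [end_time - window_days + 1, end_time], sampled at the
    field's native (daily) time steps.  Default window is 11 days.
    """
    if window_days < 2:
        raise ValueError("window_days must be >= 2")
    start = end_time - window_days + 1
    if start < sst.times[0] or end_time > sst.times[-1]:
        raise DomainError(
            f"window [{start}, {end_time}] exceeds time axis "
            f"[{sst.times[0]}, {sst.times[-1]}]"
        )
    in_window = (sst.times >= start - 1e-9) & (sst.times <= end_time + 1e-9)
    samples = [interpolate_field(sst, lat, lon, t) for t in sst.times[in_window]]
    return _stats_from_samples(samples)


# ---------------------------------------------------------------------------
# I/O: NetCDF (CF-style lat/lon/time) and long CSV (time,lat,lon,value)
# ---------------------------------------------------------------------------

def write_field_netcdf(field: GridField, path: str) -> None:
    da = xr.DataArray(
        field.values,
        coords={"time": field.times, "lat": field.lats, "lon": field.lons},
        dims=("time", "lat", "lon"),
        name="value",
        attrs={"kind": field.kind},
    )
    ds = da.to_dataset()
    if field.mask is not None:
        ds["mask"] = xr.DataArray(
            field.mask.astype("int8"), dims=("lat", "lon")
        )
    ds.to_netcdf(path, engine="scipy")


def read_field_netcdf(path: str) -> GridField:
    with xr.open_dataset(path, engine="scipy") as ds:
        da = ds["value"]
        mask = ds["mask"].values.astype(bool) if "mask" in ds else None
        return GridField(
            lats=da["lat"].values.copy(),
            lons=da["lon"].values.copy(),
            times=da["time"].values.astype(float).copy(),
            values=da.values.copy(),
            kind=str(da.attrs.get("kind", "scalar")),
            mask=mask,
        )


def write_field_csv(field: GridField, path: str) -> None:
    tt, yy, xx = np.meshgrid(field.times, field.lats, field.lons, indexing="ij")
    df = pd.DataFrame(
        {
            "time": tt.ravel(),
            "lat": yy.ravel(),
            "lon": xx.ravel(),
            "value": field.values.ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_field_csv(path: str, kind: str = "scalar") -> GridField:
    df = pd.read_csv(path)
    required = {"time", "lat", "lon", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"field CSV must have columns {sorted(required)}")
    times = np.sort(df["time"].unique())
    lats = np.sort(df["lat"].unique())
    lons = np.sort(df["lon"].unique())
    pivot = df.set_index(["time", "lat", "lon"])["value"]
    values = pivot.sort_index().to_numpy().reshape(len(times), len(lats), len(lons))
    return GridField(lats=lats, lons=lons, times=times, values=values, kind=kind)
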