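"""Staggered z-grid data model, NetCDF I/O and finite-volume validation.

The common data model used by every pipeline stage is a C-grid snapshot
series: instantaneous states (cell thickness, potential density anomaly
sigma0, tracer concentration) at times ``t_0 < t_1 < ... < t_{n-1}``, and
interval-mean face fluxes plus the biological source for every interval
``[t_k, t_{k+1}]``.  Under this convention a discrete tracer budget

    content(t_{k+1}) - content(t_k) = dt * (flux convergence + B)

can close exactly, which is what the isopycnal transform downstream relies
on.

Index conventions (stated because no standard fixes them):

* ``k`` (z) increases downward, depth positive downward;
* ``U`` lives on x-faces, shape ``(nz, ny, nx+1)``, positive eastward;
* ``V`` lives on y-faces, shape ``(nz, ny+1, nx)``, positive northward;
* ``W`` lives on z-interfaces, shape ``(nz+1, ny, nx)``, positive upward,
  with interface ``kf`` on top of cell ``kf`` and ``W[nz] = 0`` at the
  seafloor.

Canonical units are m, s, mmol (so volume fluxes are m^3 s^-1, tracer
fluxes mmol s^-1, concentrations mmol m^-3, sigma0 kg m^-3).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Sequence

import numpy as np
import xarray as xr

from .errors import GeometryError, TimeOrderingError, VariableMappingError

__all__ = [
    "GridGeometry",
    "ZGridSnapshotSeries",
    "ConsistencyReport",
    "DEFAULT_VAR_MAP",
    "read_series",
    "write_series",
    "validate_budget_consistency",
    "normalize_units",
]

# logical field -> default NetCDF variable name
DEFAULT_VAR_MAP: dict[str, str] = {
    "thickness": "h_cell",
    "sigma0": "sigma0",
    "tracer": "tracer",
    "u_flux": "u_flux",
    "v_flux": "v_flux",
    "w_flux": "w_flux",
    "fx_adv": "fx_adv",
    "fy_adv": "fy_adv",
    "fz_adv": "fz_adv",
    "fx_dif": "fx_dif",
    "fy_dif": "fy_dif",
    "fz_dif": "fz_dif",
    "bio_source": "bio_source",
    "mask": "land_mask",
}

# units accepted on input, with factors to the canonical unit
_UNIT_FACTORS: dict[str, dict[str, float]] = {
    "length": {"m": 1.0, "meters": 1.0, "cm": 1e-2, "km": 1e3},
    "volume_flux": {"m3 s-1": 1.0, "m^3/s": 1.0, "sv": 1e6, "Sv": 1e6},
    "tracer_flux": {"mmol s-1": 1.0, "mmol/s": 1.0, "mol s-1": 1e3, "mol/s": 1e3},
    "concentration": {"mmol m-3": 1.0, "mmol/m^3": 1.0, "mol m-3": 1e3},
    "density": {"kg m-3": 1.0, "kg/m^3": 1.0},
    "time": {"s": 1.0, "seconds": 1.0, "days": 86400.0},
}

_CANONICAL = {
    "length": "m",
    "volume_flux": "m3 s-1",
    "tracer_flux": "mmol s-1",
    "concentration": "mmol m-3",
    "density": "kg m-3",
    "time": "s",
}

_FIELD_KIND = {
    "thickness": "length",
    "sigma0": "density",
    "tracer": "concentration",
    "u_flux": "volume_flux",
    "v_flux": "volume_flux",
    "w_flux": "volume_flux",
    "fx_adv": "tracer_flux",
    "fy_adv": "tracer_flux",
    "fz_adv": "tracer_flux",
    "fx_dif": "tracer_flux",
    "fy_dif": "tracer_flux",
    "fz_dif": "tracer_flux",
    "bio_source": "tracer_flux",
}


def normalize_units(value: np.ndarray, units: str | None, kind: str) -> np.ndarray:
    """Convert ``value`` with unit string ``units`` to the canonical unit of
    ``kind``.  Unknown/absent unit strings are taken as already canonical, so
    the operation is idempotent."""
    if units is None:
        return value
    factor = _UNIT_FACTORS.get(kind, {}).get(units.strip())
    if factor is None or factor == 1.0:
        return value
    return value * factor


@dataclass(frozen=True)
class GridGeometry:
    """Regular lat-lon C-grid geometry.

    ``land_mask`` is a per-column boolean, True over land.  ``dz`` holds the
    nominal level thicknesses; actual thicknesses live on the series.
    """

    lat: np.ndarray        # (ny,) degrees north, cell centers
    lon: np.ndarray        # (nx,) degrees east, cell centers
    dx: np.ndarray         # (ny,) zonal cell width (m)
    dy: np.ndarray         # (ny,) meridional cell width (m)
    dz: np.ndarray         # (nz,) nominal level thickness (m)
    land_mask: np.ndarray  # (ny, nx) bool, True = land

    def __post_init__(self) -> None:
        for name in ("lat", "lon", "dx", "dy", "dz"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "land_mask", np.asarray(self.land_mask, dtype=bool))
        if self.land_mask.shape != (self.ny, self.nx):
            raise GeometryError(
                f"land_mask shape {self.land_mask.shape} != (ny, nx)=({self.ny}, {self.nx})"
            )
        for name in ("dx", "dy", "dz"):
            arr = getattr(self, name)
            if np.any(arr <= 0):
                raise GeometryError(f"{name} must be strictly positive")

    @property
    def nx(self) -> int:
        return self.lon.size

    @property
    def ny(self) -> int:
        return self.lat.size

    @property
    def nz(self) -> int:
        return self.dz.size

    @property
    def ocean(self) -> np.ndarray:
        """(ny, nx) boolean, True over ocean columns."""
        return ~self.land_mask

    @property
    def area(self) -> np.ndarray:
        """(ny, nx) horizontal cell area (m^2)."""
        return (self.dx * self.dy)[:, None] * np.ones_like(self.land_mask, dtype=float)

    @property
    def z_interfaces(self) -> np.ndarray:
        """(nz+1,) nominal interface depths, 0 at the surface."""
        return np.concatenate([[0.0], np.cumsum(self.dz)])

    @property
    def z_centers(self) -> np.ndarray:
        zi = self.z_interfaces
        return 0.5 * (zi[:-1] + zi[1:])


@dataclass
class ZGridSnapshotSeries:
    """Instantaneous states plus interval-mean fluxes on the staggered grid.

    State arrays carry ``nt`` time slices, flux/source arrays ``nt - 1``
    (one per interval between consecutive instants).
    """

    geom: GridGeometry
    times: np.ndarray    # (nt,) seconds, strictly increasing
    h: np.ndarray        # (nt, nz, ny, nx) actual cell thickness (m)
    sigma0: np.ndarray   # (nt, nz, ny, nx) potential density anomaly
    tracer: np.ndarray   # (nt, nz, ny, nx) concentration (mmol m-3)
    U: np.ndarray        # (nt-1, nz, ny, nx+1) volume flux, +east
    V: np.ndarray        # (nt-1, nz, ny+1, nx) volume flux, +north
    W: np.ndarray        # (nt-1, nz+1, ny, nx) volume flux, +up
    Fx_adv: np.ndarray   # (nt-1, nz, ny, nx+1) tracer flux (mmol s-1)
    Fy_adv: np.ndarray
    Fz_adv: np.ndarray   # (nt-1, nz+1, ny, nx)
    Fx_dif: np.ndarray
    Fy_dif: np.ndarray
    Fz_dif: np.ndarray
    B: np.ndarray        # (nt-1, nz, ny, nx) biological net source (mmol s-1)
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        nt = self.times.size
        if nt < 2:
            raise TimeOrderingError("a series needs at least two instants")
        if np.any(np.diff(self.times) <= 0):
            raise TimeOrderingError("times must be strictly increasing")
        g = self.geom
        nz, ny, nx = g.nz, g.ny, g.nx
        expected = {
            "h": (nt, nz, ny, nx),
            "sigma0": (nt, nz, ny, nx),
            "tracer": (nt, nz, ny, nx),
            "U": (nt - 1, nz, ny, nx + 1),
            "V": (nt - 1, nz, ny + 1, nx),
            "W": (nt - 1, nz + 1, ny, nx),
            "Fx_adv": (nt - 1, nz, ny, nx + 1),
            "Fy_adv": (nt - 1, nz, ny + 1, nx),
            "Fz_adv": (nt - 1, nz + 1, ny, nx),
            "Fx_dif": (nt - 1, nz, ny, nx + 1),
            "Fy_dif": (nt - 1, nz, ny + 1, nx),
            "Fz_dif": (nt - 1, nz + 1, ny, nx),
            "B": (nt - 1, nz, ny, nx),
        }
        for name, shape in expected.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise GeometryError(f"{name} has shape {arr.shape}, expected {shape}")

    @property
    def n_intervals(self) -> int:
        return self.times.size - 1

    @property
    def dt(self) -> np.ndarray:
        """(nt-1,) interval lengths in seconds."""
        return np.diff(self.times)

    def cell_volume(self, t: int) -> np.ndarray:
        """(nz, ny, nx) cell volume at instant ``t``."""
        return self.h[t] * self.geom.area[None, :, :]

    def content(self, t: int) -> np.ndarray:
        """(nz, ny, nx) tracer amount (mmol) per cell at instant ``t``."""
        return self.tracer[t] * self.cell_volume(t)

    def islice(self, k0: int, k1: int) -> "ZGridSnapshotSeries":
        """Sub-series covering intervals ``k0 .. k1-1`` (instants k0..k1)."""
        kw = {}
        for f in fields(self):
            if f.name in ("geom", "attrs"):
                continue
            arr = getattr(self, f.name)
            if f.name == "times" or arr.shape[0] == self.times.size:
                kw[f.name] = arr[k0 : k1 + 1]
            else:
                kw[f.name] = arr[k0:k1]
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# NetCDF serialization

_DIMS = {
    "h": ("time", "z", "y", "x"),
    "sigma0": ("time", "z", "y", "x"),
    "tracer": ("time", "z", "y", "x"),
    "U": ("itime", "z", "y", "xf"),
    "V": ("itime", "z", "yf", "x"),
    "W": ("itime", "zf", "y", "x"),
    "Fx_adv": ("itime", "z", "y", "xf"),
    "Fy_adv": ("itime", "z", "yf", "x"),
    "Fz_adv": ("itime", "zf", "y", "x"),
    "Fx_dif": ("itime", "z", "y", "xf"),
    "Fy_dif": ("itime", "z", "yf", "x"),
    "Fz_dif": ("itime", "zf", "y", "x"),
    "B": ("itime", "z", "y", "x"),
}

_LOGICAL_TO_ATTR = {
    "thickness": "h",
    "sigma0": "sigma0",
    "tracer": "tracer",
    "u_flux": "U",
    "v_flux": "V",
    "w_flux": "W",
    "fx_adv": "Fx_adv",
    "fy_adv": "Fy_adv",
    "fz_adv": "Fz_adv",
    "fx_dif": "Fx_dif",
    "fy_dif": "Fy_dif",
    "fz_dif": "Fz_dif",
    "bio_source": "B",
}


def series_to_dataset(series: ZGridSnapshotSeries,
                      inst: slice = slice(None),
                      intv: slice = slice(None)) -> xr.Dataset:
    """Pack (a slice of) a series into an xarray Dataset.

    ``inst`` selects instants (state arrays), ``intv`` selects intervals
    (flux/source arrays); the two are independent so a multi-file layout can
    keep the intervals spanning file boundaries.
    """
    g = series.geom
    data = {}
    for logical, attr in _LOGICAL_TO_ATTR.items():
        name = DEFAULT_VAR_MAP[logical]
        arr = np.asarray(getattr(series, attr))
        arr = arr[inst] if _DIMS[attr][0] == "time" else arr[intv]
        units = _CANONICAL[_FIELD_KIND[logical]]
        data[name] = (list(_DIMS[attr]), arr, {"units": units})
    data[DEFAULT_VAR_MAP["mask"]] = (["y", "x"], g.land_mask.astype(np.int8),
                                     {"long_name": "land mask (1=land)"})
    data["dx"] = (["y"], g.dx, {"units": "m"})
    data["dy"] = (["y"], g.dy, {"units": "m"})
    data["dz"] = (["z"], g.dz, {"units": "m"})
    coords = {
        "time": ("time", series.times[inst], {"units": "s"}),
        "itime": ("itime", series.times[:-1][intv], {"units": "s",
                  "long_name": "interval start time"}),
        "lat": ("y", g.lat, {"units": "degrees_north"}),
        "lon": ("x", g.lon, {"units": "degrees_east"}),
    }
    ds = xr.Dataset(data, coords=coords)
    ds.attrs.update(series.attrs)
    return ds


def write_series(series: ZGridSnapshotSeries, paths: str | Sequence[str],
                 attrs: Mapping[str, str] | None = None) -> list[str]:
    """Write a series to one NetCDF file, or split across several.

    With ``n`` paths the instants are split into ``n`` contiguous chunks;
    each file also carries the interval connecting it to the previous chunk,
    so that reading the files back recovers every interval (a file with k
    snapshots holds k intervals, except the first which holds k-1).
    """
    if isinstance(paths, (str, bytes)):
        paths = [paths]
    ds_attrs = dict(series.attrs)
    if attrs:
        ds_attrs.update(attrs)
    ds_attrs.setdefault("config_hash", config_hash(ds_attrs))
    nt = series.times.size
    bounds = np.array_split(np.arange(nt), len(paths))
    out = []
    for ci, idx in enumerate(bounds):
        i0, i1 = int(idx[0]), int(idx[-1])
        inst = slice(i0, i1 + 1)
        intv = slice(max(i0 - 1, 0), i1)
        ds = series_to_dataset(series, inst, intv)
        ds.attrs.update(ds_attrs)
        ds.to_netcdf(paths[ci], engine="scipy")
        out.append(paths[ci])
    return out


def read_series(paths: str | Sequence[str],
                var_map: Mapping[str, str] | None = None) -> ZGridSnapshotSeries:
    """Read a snapshot series from one or more NetCDF files.

    ``var_map`` maps logical field names (see :data:`DEFAULT_VAR_MAP`) to the
    variable names used in the files; missing keys fall back to defaults.
    Units are normalized to m / s / mmol on read; cells marked by the land
    mask are treated as land everywhere downstream.
    """
    if isinstance(paths, (str, bytes)):
        paths = [paths]
    vm = dict(DEFAULT_VAR_MAP)
    if var_map:
        vm.update(var_map)
    dsets = [xr.open_dataset(p, engine="scipy") for p in paths]
    try:
        for key in vm:
            if key == "mask":
                continue
            for p, ds in zip(paths, dsets):
                if vm[key] not in ds.variables:
                    raise VariableMappingError(
                        f"required field {key!r} (variable {vm[key]!r}) missing from {p}"
                    )
        shapes = {ds[vm["tracer"]].shape[1:] for ds in dsets}
        if len(shapes) != 1:
            raise GeometryError(f"inconsistent grid shapes across files: {sorted(shapes)}")
        state = xr.concat([ds[[vm[k] for k in
                               ("thickness", "sigma0", "tracer")]] for ds in dsets],
                          dim="time")
        flux_keys = ("u_flux", "v_flux", "w_flux", "fx_adv", "fy_adv", "fz_adv",
                     "fx_dif", "fy_dif", "fz_dif", "bio_source")
        fluxes = xr.concat([ds[[vm[k] for k in flux_keys]] for ds in dsets], dim="itime")
        first = dsets[0]
        times = np.asarray(state["time"].values, dtype=float)
        order = np.argsort(times, kind="stable")
        times = times[order]
        if np.any(np.diff(times) <= 0):
            raise TimeOrderingError("snapshot times are not strictly increasing")
        state = state.isel(time=order)
        itimes = np.asarray(fluxes["itime"].values, dtype=float)
        iorder = np.argsort(itimes, kind="stable")
        fluxes = fluxes.isel(itime=iorder)
        itimes = itimes[iorder]
        if itimes.size != times.size - 1 or not np.allclose(itimes, times[:-1]):
            raise TimeOrderingError(
                "interval start times do not match instants (expected one "
                "interval per consecutive pair of snapshots)")

        mask_name = vm["mask"]
        if mask_name in first.variables:
            land = np.asarray(first[mask_name].values).astype(bool)
        else:
            land = ~np.isfinite(np.asarray(state[vm["tracer"]].isel(time=0, z=0).values))
        geom = GridGeometry(
            lat=np.asarray(first["lat"].values, dtype=float),
            lon=np.asarray(first["lon"].values, dtype=float),
            dx=np.asarray(first["dx"].values, dtype=float),
            dy=np.asarray(first["dy"].values, dtype=float),
            dz=np.asarray(first["dz"].values, dtype=float),
            land_mask=land,
        )

        def _get(dset, key):
            da = dset[vm[key]]
            arr = np.asarray(da.values, dtype=float)
            arr = normalize_units(arr, da.attrs.get("units"), _FIELD_KIND[key])
            return np.nan_to_num(arr, nan=0.0) if key != "sigma0" else arr

        series = ZGridSnapshotSeries(
            geom=geom,
            times=times,
            h=_get(state, "thickness"),
            sigma0=_get(state, "sigma0"),
            tracer=_get(state, "tracer"),
            U=_get(fluxes, "u_flux"),
            V=_get(fluxes, "v_flux"),
            W=_get(fluxes, "w_flux"),
            Fx_adv=_get(fluxes, "fx_adv"),
            Fy_adv=_get(fluxes, "fy_adv"),
            Fz_adv=_get(fluxes, "fz_adv"),
            Fx_dif=_get(fluxes, "fx_dif"),
            Fy_dif=_get(fluxes, "fy_dif"),
            Fz_dif=_get(fluxes, "fz_dif"),
            B=_get(fluxes, "bio_source"),
            attrs=dict(first.attrs),
        )
        return series
    finally:
        for ds in dsets:
            ds.close()


# ---------------------------------------------------------------------------
# Finite-volume consistency validation


def tracer_budget_residual(series: ZGridSnapshotSeries, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell z-level tracer budget residual for interval ``k`` and the
    scale used to normalize it (gross term magnitude)."""
    dt = series.times[k + 1] - series.times[k]
    dC = series.content(k + 1) - series.content(k)
    conv = (series.Fx_adv[k][:, :, :-1] - series.Fx_adv[k][:, :, 1:]
            + series.Fx_dif[k][:, :, :-1] - series.Fx_dif[k][:, :, 1:]
            + series.Fy_adv[k][:, :-1, :] - series.Fy_adv[k][:, 1:, :]
            + series.Fy_dif[k][:, :-1, :] - series.Fy_dif[k][:, 1:, :]
            + series.Fz_adv[k][1:, :, :] - series.Fz_adv[k][:-1, :, :]
            + series.Fz_dif[k][1:, :, :] - series.Fz_dif[k][:-1, :, :])
    resid = dC - dt * (conv + series.B[k])
    gross = dt * (np.abs(series.Fx_adv[k][:, :, :-1]) + np.abs(series.Fx_adv[k][:, :, 1:])
                  + np.abs(series.Fy_adv[k][:, :-1, :]) + np.abs(series.Fy_adv[k][:, 1:, :])
                  + np.abs(series.Fz_adv[k][1:, :, :]) + np.abs(series.Fz_adv[k][:-1, :, :])
                  + np.abs(series.B[k]))
    scale = np.maximum.reduce([np.abs(dC), gross,
                               np.abs(series.content(k)) * 1e-6])
    scale = np.maximum(scale, 1e-300)
    return resid, scale


def volume_budget_residual(series: ZGridSnapshotSeries, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell volume budget residual for interval ``k`` (thickness tendency
    vs volume-flux convergence) and its normalization scale."""
    area = series.geom.area[None, :, :]
    dt = series.times[k + 1] - series.times[k]
    dV = (series.h[k + 1] - series.h[k]) * area
    conv = (series.U[k][:, :, :-1] - series.U[k][:, :, 1:]
            + series.V[k][:, :-1, :] - series.V[k][:, 1:, :]
            + series.W[k][1:, :, :] - series.W[k][:-1, :, :])
    resid = dV - dt * conv
    gross = dt * (np.abs(series.U[k][:, :, :-1]) + np.abs(series.U[k][:, :, 1:])
                  + np.abs(series.V[k][:, :-1, :]) + np.abs(series.V[k][:, 1:, :])
                  + np.abs(series.W[k][1:, :, :]) + np.abs(series.W[k][:-1, :, :]))
    scale = np.maximum.reduce([np.abs(dV), gross, series.h[k] * area * 1e-6])
    scale = np.maximum(scale, 1e-300)
    return resid, scale


@dataclass
class ConsistencyReport:
    """Outcome of :func:`validate_budget_consistency` (report only; no
    exception is raised on failure)."""

    tol: float
    tracer_max_rel: np.ndarray   # (n_intervals,)
    volume_max_rel: np.ndarray   # (n_intervals,)
    n_flagged_tracer: int
    n_flagged_volume: int

    @property
    def max_rel(self) -> float:
        return float(max(self.tracer_max_rel.max(initial=0.0),
                         self.volume_max_rel.max(initial=0.0)))

    @property
    def passed(self) -> bool:
        return self.n_flagged_tracer == 0 and self.n_flagged_volume == 0

    def to_dict(self) -> dict:
        return {
            "tol": self.tol,
            "max_rel_residual": self.max_rel,
            "tracer_max_rel_per_interval": self.tracer_max_rel.tolist(),
            "volume_max_rel_per_interval": self.volume_max_rel.tolist(),
            "n_flagged_tracer": self.n_flagged_tracer,
            "n_flagged_volume": self.n_flagged_volume,
            "passed": self.passed,
        }


def validate_budget_consistency(series: ZGridSnapshotSeries,
                                tol: float = 1e-10) -> ConsistencyReport:
    """Check that the z-level tracer and volume budgets close for every
    interval, relative to the gross magnitude of the participating terms."""
    ocean = series.geom.ocean[None, :, :]
    t_max = np.zeros(series.n_intervals)
    v_max = np.zeros(series.n_intervals)
    n_t = 0
    n_v = 0
    for k in range(series.n_intervals):
        resid, scale = tracer_budget_residual(series, k)
        rel = np.where(ocean, np.abs(resid) / scale, 0.0)
        t_max[k] = rel.max()
        n_t += int((rel > tol).sum())
        resid, scale = volume_budget_residual(series, k)
        rel = np.where(ocean, np.abs(resid) / scale, 0.0)
        v_max[k] = rel.max()
        n_v += int((rel > tol).sum())
    return ConsistencyReport(tol=tol, tracer_max_rel=t_max, volume_max_rel=v_max,
                             n_flagged_tracer=n_t, n_flagged_volume=n_v)


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
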