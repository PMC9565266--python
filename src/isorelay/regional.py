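"""Regional nutrient-budget analyses: zonally closed latitude-band budgets,
the gyre-interior (deep-isopycnal) mask, masked budgets, and land-aware
Gaussian smoothing of convergence maps.

Sign convention for boundary fluxes: positive into the region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .budget import BudgetTable
from .density_layers import isopycnal_depth, _refinement_plan, \
    _interp_to_fine, _uniform_profile
from .errors import RegionError
from .grid_io import GridGeometry, ZGridSnapshotSeries
from .reynolds import ReynoldsFluxes

__all__ = [
    "RegionSpec",
    "band_budget",
    "gyre_interior_mask",
    "masked_budget",
    "smooth_gaussian",
]


@dataclass(frozen=True)
class RegionSpec:
    """Region used for budget integration.

    ``lat_band``: columns with lat_bounds[0] < lat < lat_bounds[1], closed
    coast-to-coast in x.  ``isopycnal_depth_mask``: columns where the
    sigma_ref isopycnal lies strictly deeper than depth_threshold.
    ``custom_mask``: an explicit column mask.
    """

    kind: str = "lat_band"
    lat_bounds: tuple[float, float] = (12.0, 42.0)
    sigma_ref: float = 26.8
    depth_threshold: float = 450.0
    mask: np.ndarray | None = None
    #: optional zonal restriction (degrees); None = coast to coast
    lon_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("lat_band", "isopycnal_depth_mask", "custom_mask"):
            raise RegionError(f"unknown region kind {self.kind!r}")
        if self.lat_bounds[0] >= self.lat_bounds[1]:
            raise RegionError("lat_bounds must be increasing")
        if self.depth_threshold <= 0:
            raise RegionError("depth_threshold must be positive")
        if self.kind == "custom_mask" and self.mask is None:
            raise RegionError("custom_mask region needs a mask")


def _band_rows(geom: GridGeometry, region: RegionSpec) -> np.ndarray:
    rows = np.nonzero((geom.lat > region.lat_bounds[0])
                      & (geom.lat < region.lat_bounds[1]))[0]
    if rows.size == 0:
        raise RegionError(f"no grid rows inside latitude band {region.lat_bounds}")
    if np.any(np.diff(rows) != 1):
        raise RegionError("latitude band rows are not contiguous")
    return rows


def _band_cols(geom: GridGeometry, region: RegionSpec) -> np.ndarray:
    if region.lon_bounds is None:
        return np.arange(geom.nx)
    cols = np.nonzero((geom.lon > region.lon_bounds[0])
                      & (geom.lon < region.lon_bounds[1]))[0]
    if cols.size == 0:
        raise RegionError(f"no grid columns inside {region.lon_bounds}")
    return cols


def _check_zonal_closure(geom: GridGeometry, rows: np.ndarray,
                         cols: np.ndarray) -> None:
    """Coast-to-coast requirement: the band's zonal edges must be land or
    the closed domain boundary in every row; otherwise zonal along-layer
    transport would leak through the budget.  Refuses, naming the open
    columns, rather than silently including the leakage."""
    land = geom.land_mask
    open_cols = []
    for j in rows:
        in_band = np.zeros(geom.nx, dtype=bool)
        in_band[cols] = True
        ocean_i = np.nonzero(~land[j] & in_band)[0]
        if ocean_i.size == 0:
            continue
        # domain boundary counts as coast
        if ocean_i[0] > 0 and not land[j, ocean_i[0] - 1]:
            open_cols.append((int(j), int(ocean_i[0])))
        if ocean_i[-1] < land.shape[1] - 1 and not land[j, ocean_i[-1] + 1]:
            open_cols.append((int(j), int(ocean_i[-1])))
    if open_cols:
        raise RegionError(f"band is not zonally closed at columns {open_cols}")


def band_budget(table: BudgetTable, reyn: ReynoldsFluxes,
                region: RegionSpec | None = None) -> pd.DataFrame:
    """Basin-band budget: macro-layer terms integrated over a zonally closed
    latitude band, with the physical source split into diapycnal, isopycnal
    mean and isopycnal eddy convergences, and the meridional boundary
    transports (positive into the band) at both latitude bounds.

    ``table`` is a fine-layer per-column budget; the mean/eddy convergences
    are taken from ``reyn``.  Rows of the result are the macro layers.
    """
    region = region or RegionSpec()
    geom = table.geom
    grid = table.grid
    rows = _band_rows(geom, region)
    cols = _band_cols(geom, region)
    _check_zonal_closure(geom, rows, cols)
    ifaces = grid.macro_interfaces()
    nm = len(ifaces) - 1

    mean_conv = reyn.iso_convergence("mean")
    eddy_conv = reyn.iso_convergence("eddy")

    def integrate(arr: np.ndarray) -> np.ndarray:
        grouped = np.add.reduceat(arr, ifaces[:-1], axis=0)
        return grouped[np.ix_(np.arange(nm), rows, cols)].sum(axis=(1, 2))

    js, jn = int(rows[0]), int(rows[-1] + 1)   # bounding y-faces

    def boundary(Ty: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        grouped = np.add.reduceat(Ty, ifaces[:-1], axis=0)
        south_in = grouped[:, js, :][:, cols].sum(axis=1)   # +north = into band
        north_in = -grouped[:, jn, :][:, cols].sum(axis=1)
        return south_in, north_in

    bio = integrate(table.bio)
    tendency = integrate(table.tendency)
    dia = integrate(table.dia_conv)
    iso_mean = integrate(mean_conv)
    iso_eddy = integrate(eddy_conv)
    iso_total = integrate(table.iso_conv)
    s_mean, n_mean = boundary(reyn.Ty_mean)
    s_eddy, n_eddy = boundary(reyn.Ty_eddy)

    # with a zonally closed band the meridional boundary transports are the
    # whole isopycnal term; verify the zonal remainder is negligible
    zonal = iso_total - (s_mean + n_mean + s_eddy + n_eddy)
    scale = max(np.abs(bio).max(), np.abs(dia).max(), np.abs(iso_total).max(),
                np.abs(tendency).max(), 1e-300)
    if np.abs(zonal).max() > 1e-9 * scale:
        raise RegionError(
            f"zonal flux contribution {np.abs(zonal).max():.3e} exceeds "
            f"1e-9 of the largest budget term ({scale:.3e})")

    names = (table.layer_names if table.layer_names and len(table.layer_names) == nm
             else ("surface", "upper thermocline", "lower thermocline",
                   "abyssal remainder")[:nm])
    if len(names) != nm:
        names = tuple(f"macro_{i}" for i in range(nm))
    df = pd.DataFrame({
        "layer": list(names),
        "bio": bio, "tendency": tendency,
        "physical": dia + iso_mean + iso_eddy,
        "dia_conv": dia, "iso_mean_conv": iso_mean, "iso_eddy_conv": iso_eddy,
        "south_mean_in": s_mean, "south_eddy_in": s_eddy,
        "north_mean_in": n_mean, "north_eddy_in": n_eddy,
    })
    return df


def gyre_interior_mask(series: ZGridSnapshotSeries,
                       region: RegionSpec | None = None,
                       target_dz: float = 2.0) -> np.ndarray:
    """Columns where the time-mean ``sigma_ref`` isopycnal lies strictly
    deeper than ``depth_threshold`` (False where it outcrops, is missing, or
    over land)."""
    region = region or RegionSpec(kind="isopycnal_depth_mask")
    geom = series.geom
    sig_mean = series.sigma0.mean(axis=0)
    prof = _uniform_profile(series.h[0], geom.ocean)
    plan = _refinement_plan(prof, target_dz)
    sig_fine = _interp_to_fine(sig_mean, plan)
    depth = isopycnal_depth(sig_fine, plan.fine_center, region.sigma_ref)
    with np.errstate(invalid="ignore"):
        mask = np.where(np.isnan(depth), False, depth > region.depth_threshold)
    return mask & geom.ocean


def masked_budget(table: BudgetTable, reyn: ReynoldsFluxes,
                  mask: np.ndarray) -> pd.DataFrame:
    """Macro-layer budget integrated over an arbitrary column mask.

    Lateral transport across the (jagged) mask edge is reported through the
    integrated convergences: the net along-layer transport into the region
    equals the integral of the convergence over it, split into mean and
    eddy parts.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise RegionError("empty region mask")
    grid = table.grid
    ifaces = grid.macro_interfaces()
    nm = len(ifaces) - 1

    def integrate(arr: np.ndarray) -> np.ndarray:
        grouped = np.add.reduceat(arr, ifaces[:-1], axis=0)
        return grouped[:, mask].sum(axis=1)

    bio = integrate(table.bio)
    tendency = integrate(table.tendency)
    dia = integrate(table.dia_conv)
    iso_mean = integrate(reyn.iso_convergence("mean"))
    iso_eddy = integrate(reyn.iso_convergence("eddy"))
    names = ("surface", "upper thermocline", "lower thermocline",
             "abyssal remainder")[:nm]
    if len(names) != nm:
        names = tuple(f"macro_{i}" for i in range(nm))
    return pd.DataFrame({
        "layer": list(names),
        "bio": bio, "tendency": tendency,
        "physical": dia + iso_mean + iso_eddy,
        "dia_conv": dia, "iso_mean_conv": iso_mean, "iso_eddy_conv": iso_eddy,
        "lateral_mean_in": iso_mean, "lateral_eddy_in": iso_eddy,
    })


def smooth_gaussian(field: np.ndarray, land_mask: np.ndarray | None = None,
                    sd_gridpoints: float = 1.0) -> np.ndarray:
    """Land-aware 2-D Gaussian smoothing (SD in grid points, truncated at
    4 SD): kernel weights falling on land are renormalized over ocean, so a
    constant ocean field is unchanged and the ocean integral is preserved up
    to kernel truncation."""
    field = np.asarray(field, dtype=float)
    if sd_gridpoints <= 0:
        return field.copy()
    if land_mask is None:
        ocean = np.ones(field.shape, dtype=bool)
    else:
        ocean = ~np.asarray(land_mask, dtype=bool)
    filled = np.where(ocean, field, 0.0)
    num = ndimage.gaussian_filter(filled, sd_gridpoints, mode="constant",
                                  truncate=4.0)
    den = ndimage.gaussian_filter(ocean.astype(float), sd_gridpoints,
                                  mode="constant", truncate=4.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(ocean & (den > 0), num / np.where(den > 0, den, 1.0),
                       np.nan)
    return out
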