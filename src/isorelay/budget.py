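"""Term-by-term assembly of the layer tracer balance and closure checks.

Per density layer and grid column, the balance reads

    tendency = iso_conv + dia_conv + bio - residual

with the tendency from endpoint layer contents over the averaging window,
the isopycnal convergence from along-layer face-transport differences, the
diapycnal convergence from the interface fluxes, and the biological source
from the layer-integrated rate.  On input whose z-level budgets close, the
residual is round-off by construction of the layered transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .density_layers import DensityGrid, LayeredFields
from .grid_io import GridGeometry

__all__ = [
    "BudgetTable",
    "layer_budget",
    "implied_bio_flux",
    "aggregate_macro",
]

MACRO_LAYER_NAMES = ("surface", "upper thermocline", "lower thermocline",
                     "abyssal remainder")


@dataclass
class BudgetTable:
    """Layer budget terms per column (mmol s-1), plus interface fluxes.

    ``layer_edges`` records the bounding sigma0 values per layer as
    (lower, upper) with NaN for the open surface/bottom bins.
    """

    grid: DensityGrid
    geom: GridGeometry
    tendency: np.ndarray    # (nl, ny, nx)
    iso_conv: np.ndarray
    dia_conv: np.ndarray
    bio: np.ndarray
    residual: np.ndarray
    Fd: np.ndarray          # (nl+1, ny, nx) interface tracer flux, +up
    window_seconds: float
    iso_mean_conv: np.ndarray | None = None
    iso_eddy_conv: np.ndarray | None = None
    layer_names: tuple[str, ...] | None = None
    attrs: dict = field(default_factory=dict)

    @property
    def n_layers(self) -> int:
        return self.tendency.shape[0]

    def max_rel_residual(self) -> float:
        scale = max(np.abs(self.tendency).max(), np.abs(self.iso_conv).max(),
                    np.abs(self.dia_conv).max(), np.abs(self.bio).max(), 1e-300)
        return float(np.abs(self.residual).max() / scale)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (layer, term, y, x, value) table."""
        terms = {"tendency": self.tendency, "iso_conv": self.iso_conv,
                 "dia_conv": self.dia_conv, "bio": self.bio,
                 "residual": self.residual}
        if self.iso_mean_conv is not None:
            terms["iso_mean_conv"] = self.iso_mean_conv
            terms["iso_eddy_conv"] = self.iso_eddy_conv
        rows = []
        for name, arr in terms.items():
            for l in range(self.n_layers):
                lab = (self.layer_names[l] if self.layer_names
                       else f"layer_{l}")
                rows.append({"layer": lab, "term": name,
                             "value": float(arr[l].sum())})
        return pd.DataFrame(rows)


def _check_uniform_dt(layered: Sequence[LayeredFields]) -> float:
    dts = np.array([lf.dt for lf in layered])
    if not np.allclose(dts, dts[0], rtol=1e-9):
        raise ValueError("layer_budget requires uniform interval lengths")
    return float(dts[0])


def layer_budget(layered: Sequence[LayeredFields],
                 iso_mean_conv: np.ndarray | None = None,
                 iso_eddy_conv: np.ndarray | None = None) -> BudgetTable:
    """Assemble the per-layer, per-column budget over a window of intervals.

    The tendency uses the endpoint contents of the window (telescoping sum
    of per-interval tendencies); the flux terms are arithmetic time means.
    An optional mean/eddy split of the isopycnal convergence (from the
    Reynolds decomposition) is attached when supplied.
    """
    if len(layered) == 0:
        raise ValueError("empty layered series")
    dt = _check_uniform_dt(layered)
    n = len(layered)
    window = dt * n
    tendency = (layered[-1].content1 - layered[0].content0) / window
    iso = np.mean([lf.iso_convergence() for lf in layered], axis=0)
    dia = np.mean([lf.dia_convergence() for lf in layered], axis=0)
    bio = np.mean([lf.S for lf in layered], axis=0)
    Fd = np.mean([lf.Fd for lf in layered], axis=0)
    residual = iso + dia + bio - tendency
    return BudgetTable(
        grid=layered[0].grid, geom=layered[0].geom,
        tendency=tendency, iso_conv=iso, dia_conv=dia, bio=bio,
        residual=residual, Fd=Fd, window_seconds=window,
        iso_mean_conv=iso_mean_conv, iso_eddy_conv=iso_eddy_conv,
        attrs=dict(layered[0].attrs, n_intervals=n),
    )


def implied_bio_flux(bio: np.ndarray) -> np.ndarray:
    """Implied vertical biogeochemical flux profile from the layer sources.

    Cumulative integral of the layer-integrated source from the surface
    down with a no-flux condition at the surface: the flux through the
    bottom interface of layer ``l`` is the flux through its top plus the
    source in ``l``.  Negative values are downward transfer (e.g. sinking
    particles feeding remineralization below).

    ``bio`` has the layer axis first (surface layer first); the result has
    one more entry along that axis (interfaces).
    """
    bio = np.asarray(bio, dtype=float)
    out = np.zeros((bio.shape[0] + 1,) + bio.shape[1:])
    out[1:] = np.cumsum(bio, axis=0)
    return out


def aggregate_macro(table: BudgetTable,
                    macro_edges: Sequence[float] | None = None) -> BudgetTable:
    """Aggregate a fine-layer budget into the macro layers (surface, upper
    and lower thermocline, abyssal remainder by default).

    Terms are summed within each macro layer; interface fluxes are taken at
    the macro edges only.  Aggregation commutes with budget assembly.
    """
    grid = table.grid
    if macro_edges is not None:
        grid = DensityGrid(edges=grid.edges, macro_edges=tuple(macro_edges))
    ifaces = grid.macro_interfaces()
    nm = len(ifaces) - 1

    def agg(arr: np.ndarray) -> np.ndarray:
        return np.add.reduceat(arr, ifaces[:-1], axis=0)

    names = (MACRO_LAYER_NAMES if nm == len(MACRO_LAYER_NAMES)
             else tuple(f"macro_{i}" for i in range(nm)))
    return BudgetTable(
        grid=grid, geom=table.geom,
        tendency=agg(table.tendency), iso_conv=agg(table.iso_conv),
        dia_conv=agg(table.dia_conv), bio=agg(table.bio),
        residual=agg(table.residual), Fd=table.Fd[ifaces],
        window_seconds=table.window_seconds,
        iso_mean_conv=None if table.iso_mean_conv is None else agg(table.iso_mean_conv),
        iso_eddy_conv=None if table.iso_eddy_conv is None else agg(table.iso_eddy_conv),
        layer_names=names,
        attrs=dict(table.attrs, macro_edges=tuple(grid.macro_edges)),
    )
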