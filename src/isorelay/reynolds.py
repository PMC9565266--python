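"""Reynolds (mean/eddy) decomposition of time-mean layer transports.

The total time-mean along-layer tracer transport through each face splits
into a mean component, built from the product of time means at a fixed
position, and an eddy component defined as the exact residual, so

    total = mean + eddy          (bitwise, by construction).

The time means entering the mean component are thickness-weighted: the
layer velocity is realized through the time-mean layer volume transport,
and the face tracer concentration through the per-interval transport-
weighted face concentration ``T_adv / V`` (falling back to the
layer-content-derived concentration of the adjacent columns for intervals
with no volume transport through the face).  Under this weighting the eddy
component vanishes identically whenever the flow field and the layer
geometry are steady, however the tracer itself may drift — fluctuations of
velocity or thickness are what make an eddy flux.  Parameterized
along-layer diffusive transports are part of the total but not of the mean
product, so they land in the eddy residual.

The biological source is decomposed the same way: the total time-mean layer
source splits into the product of independently averaged layer thickness
and intensive source rate plus a residual capturing thickness–rate
covariance (heaving rectification).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields as dc_fields
from typing import Sequence

import numpy as np

from .density_layers import LayeredFields
from .errors import GeometryError

__all__ = [
    "ReynoldsFluxes",
    "time_mean_layers",
    "mean_component",
    "eddy_component",
    "bio_source_decomposition",
    "reynolds_decompose",
]

_MEANED_FIELDS = ("h0", "h1", "content0", "content1", "Tx_adv", "Tx_dif",
                  "Ty_adv", "Ty_dif", "Vx", "Vy", "Wd", "Fd", "Fd_dif", "S",
                  "edge_depth")


@dataclass
class ReynoldsFluxes:
    """Mean/eddy split of the time-mean layer transports and source.

    ``total = mean + eddy`` and ``bio_total = bio_mean + bio_eddy`` hold
    bitwise; with a single sample every eddy field is exactly zero.
    """

    Tx_total: np.ndarray   # (nl, ny, nx+1) mmol s-1
    Tx_mean: np.ndarray
    Tx_eddy: np.ndarray
    Ty_total: np.ndarray   # (nl, ny+1, nx)
    Ty_mean: np.ndarray
    Ty_eddy: np.ndarray
    bio_total: np.ndarray  # (nl, ny, nx) mmol s-1
    bio_mean: np.ndarray
    bio_eddy: np.ndarray
    n_samples: int
    attrs: dict = field(default_factory=dict)

    def iso_convergence(self, which: str = "total") -> np.ndarray:
        """(nl, ny, nx) along-layer flux convergence of the chosen part."""
        Tx = getattr(self, f"Tx_{which}")
        Ty = getattr(self, f"Ty_{which}")
        return (Tx[:, :, :-1] - Tx[:, :, 1:] + Ty[:, :-1, :] - Ty[:, 1:, :])


def time_mean_layers(layered: Sequence[LayeredFields]) -> LayeredFields:
    """Arithmetic mean over intervals of every layered quantity at fixed
    (layer, column) — the overbar of the decomposition."""
    if len(layered) == 0:
        raise ValueError("cannot average an empty layered series")
    first = layered[0]
    kw = {f.name: getattr(first, f.name) for f in dc_fields(first)
          if f.name not in _MEANED_FIELDS}
    n = len(layered)
    for name in _MEANED_FIELDS:
        stack = np.stack([getattr(lf, name) for lf in layered])
        if name == "edge_depth":
            # NaN marks outcropped edges; all-NaN stays NaN
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                kw[name] = np.nanmean(stack, axis=0)
        else:
            kw[name] = stack.mean(axis=0)
    kw["n_samples"] = n
    kw["dt"] = float(np.mean([lf.dt for lf in layered]))
    kw["attrs"] = dict(first.attrs, n_samples=n)
    return LayeredFields(**kw)


def _layer_concentration(lf: LayeredFields) -> np.ndarray:
    """(nl, ny, nx) layer-mean concentration content/(h*area), 0 where the
    layer has vanished."""
    vol = lf.h * lf.geom.area[None]
    with np.errstate(invalid="ignore", divide="ignore"):
        conc = np.where(vol > 0, lf.content / np.where(vol > 0, vol, 1.0), 0.0)
    return conc


def _face_concentration(lf: LayeredFields, axis: str) -> np.ndarray:
    """Per-interval face concentration: transport-weighted where the face
    carries volume transport, otherwise the average of the adjacent columns'
    content-derived concentrations (ignoring vanished sides)."""
    conc = _layer_concentration(lf)
    h = lf.h
    if axis == "x":
        V, T = lf.Vx, lf.Tx_adv
        cl, cr = conc[:, :, :-1], conc[:, :, 1:]
        hl, hr = h[:, :, :-1], h[:, :, 1:]
        pad = ((0, 0), (0, 0), (1, 1))
    else:
        V, T = lf.Vy, lf.Ty_adv
        cl, cr = conc[:, :-1, :], conc[:, 1:, :]
        hl, hr = h[:, :-1, :], h[:, 1:, :]
        pad = ((0, 0), (1, 1), (0, 0))
    wsum = hl + hr
    with np.errstate(invalid="ignore", divide="ignore"):
        content_based = np.where(wsum > 0,
                                 (hl * cl + hr * cr) / np.where(wsum > 0, wsum, 1.0),
                                 0.0)
    content_based = np.pad(content_based, pad)
    with np.errstate(invalid="ignore", divide="ignore"):
        transport_based = np.where(V != 0, T / np.where(V != 0, V, 1.0), 0.0)
    return np.where(V != 0, transport_based, content_based)


def mean_component(layered: Sequence[LayeredFields]) -> tuple[np.ndarray, np.ndarray]:
    """Mean along-layer transport per face: (time-mean volume transport) x
    (time-mean face concentration).  Faces of always-vanished layers give 0.
    Returns ``(Tx_mean, Ty_mean)``."""
    if len(layered) == 0:
        raise ValueError("cannot decompose an empty layered series")
    Vx = np.mean([lf.Vx for lf in layered], axis=0)
    Vy = np.mean([lf.Vy for lf in layered], axis=0)
    px = np.mean([_face_concentration(lf, "x") for lf in layered], axis=0)
    py = np.mean([_face_concentration(lf, "y") for lf in layered], axis=0)
    return Vx * px, Vy * py


def eddy_component(total: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Eddy transport as the exact residual total - mean."""
    total = np.asarray(total)
    mean = np.asarray(mean)
    if total.shape != mean.shape:
        raise GeometryError(f"shape mismatch: {total.shape} vs {mean.shape}")
    return total - mean


def bio_source_decomposition(
        layered: Sequence[LayeredFields]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split the time-mean layer biological source into the product of
    independently averaged thickness and intensive rate, plus the residual
    (thickness–rate covariance from isopycnal heaving).

    Returns ``(bio_total, bio_mean, bio_eddy)``, each (nl, ny, nx) in
    mmol s-1, with ``bio_total = bio_mean + bio_eddy`` bitwise.
    """
    if len(layered) == 0:
        raise ValueError("cannot decompose an empty layered series")
    area = layered[0].geom.area[None]
    S_bar = np.mean([lf.S for lf in layered], axis=0)
    h_bar = np.mean([lf.h for lf in layered], axis=0)

    def rate(lf: LayeredFields) -> np.ndarray:
        vol = lf.h * area
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(vol > 0, lf.S / np.where(vol > 0, vol, 1.0), 0.0)

    b_bar = np.mean([rate(lf) for lf in layered], axis=0)
    bio_mean = h_bar * b_bar * area
    return S_bar, bio_mean, S_bar - bio_mean


def reynolds_decompose(layered: Sequence[LayeredFields]) -> ReynoldsFluxes:
    """Full mean/eddy decomposition of a layered interval series."""
    Tx_total = np.mean([lf.Tx for lf in layered], axis=0)
    Ty_total = np.mean([lf.Ty for lf in layered], axis=0)
    if len(layered) == 1:
        # a single sample has no fluctuations by definition
        Tx_mean, Ty_mean = Tx_total.copy(), Ty_total.copy()
    else:
        Tx_mean, Ty_mean = mean_component(layered)
    Tx_eddy = eddy_component(Tx_total, Tx_mean)
    Ty_eddy = eddy_component(Ty_total, Ty_mean)
    bio_total, bio_mean, bio_eddy = bio_source_decomposition(layered)
    if len(layered) == 1:
        bio_mean = bio_total.copy()
        bio_eddy = np.zeros_like(bio_total)
    return ReynoldsFluxes(
        Tx_total=Tx_total, Tx_mean=Tx_mean, Tx_eddy=Tx_eddy,
        Ty_total=Ty_total, Ty_mean=Ty_mean, Ty_eddy=Ty_eddy,
        bio_total=bio_total, bio_mean=bio_mean, bio_eddy=bio_eddy,
        n_samples=len(layered),
        attrs={
            "velocity_weighting": "transport-derived (thickness-weighted)",
            "face_concentration": "transport-weighted, content-derived fallback",
            "diffusive_transports": "included in total, excluded from mean",
        },
    )
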