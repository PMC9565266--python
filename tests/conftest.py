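"""Shared fixtures: generator runs are expensive, so the full-size relay
simulation and its layered transform are session-scoped and reused by the
unit and acceptance tests."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

import isorelay as ir


@pytest.fixture(scope="session")
def relay_cfg() -> ir.SyntheticConfig:
    return ir.relay_scenario(seed=0)


@pytest.fixture(scope="session")
def relay_series(relay_cfg) -> ir.ZGridSnapshotSeries:
    """Equilibrated relay run at full study size: 40x40x20, 60 diagnosed
    3-day intervals after 40 intervals of spin-up."""
    return ir.run_forward(relay_cfg, n_intervals=60, spinup_intervals=40)


@pytest.fixture(scope="session")
def density_grid() -> ir.DensityGrid:
    return ir.default_density_grid()


@pytest.fixture(scope="session")
def relay_layered(relay_series, density_grid):
    return ir.bin_series(relay_series, density_grid, target_dz=2.0)


@pytest.fixture(scope="session")
def relay_reynolds(relay_layered) -> ir.ReynoldsFluxes:
    return ir.reynolds_decompose(relay_layered)


@pytest.fixture(scope="session")
def relay_budget(relay_layered, relay_reynolds) -> ir.BudgetTable:
    return ir.layer_budget(relay_layered,
                           iso_mean_conv=relay_reynolds.iso_convergence("mean"),
                           iso_eddy_conv=relay_reynolds.iso_convergence("eddy"))


@pytest.fixture(scope="session")
def interior_mask(relay_series) -> np.ndarray:
    return ir.gyre_interior_mask(relay_series)


@pytest.fixture(scope="session")
def small_cfg() -> ir.SyntheticConfig:
    """Down-scaled basin for cheap unit tests."""
    return replace(ir.relay_scenario(seed=1), nx=16, ny=16, nz=10,
                   n_shallow=5, gyre_strength=8e6, eddy_amplitude=4e6,
                   overturning_strength=1.5e6)


@pytest.fixture(scope="session")
def small_series(small_cfg) -> ir.ZGridSnapshotSeries:
    return ir.run_forward(small_cfg, n_intervals=6, spinup_intervals=2)


def quiescent_series(nz=4, ny=3, nx=3, nt=2, dt=3600.0, tracer=1.0,
                     sigma_span=(23.5, 27.2), dz=None):
    """Motionless, sourceless, perfectly steady series on a small grid."""
    dz = np.linspace(10.0, 40.0, nz) if dz is None else np.asarray(dz, float)
    geom = ir.GridGeometry(lat=np.linspace(10, 12, ny),
                           lon=np.linspace(150, 152, nx),
                           dx=np.full(ny, 1e5), dy=np.full(ny, 1e5), dz=dz,
                           land_mask=np.zeros((ny, nx), dtype=bool))
    times = dt * np.arange(nt)
    shape = (nt, nz, ny, nx)
    sig = np.linspace(*sigma_span, nz)[None, :, None, None]
    return ir.ZGridSnapshotSeries(
        geom=geom, times=times,
        h=np.broadcast_to(dz[None, :, None, None], shape).copy(),
        sigma0=np.broadcast_to(sig, shape).copy(),
        tracer=np.full(shape, float(tracer)),
        U=np.zeros((nt - 1, nz, ny, nx + 1)),
        V=np.zeros((nt - 1, nz, ny + 1, nx)),
        W=np.zeros((nt - 1, nz + 1, ny, nx)),
        Fx_adv=np.zeros((nt - 1, nz, ny, nx + 1)),
        Fy_adv=np.zeros((nt - 1, nz, ny + 1, nx)),
        Fz_adv=np.zeros((nt - 1, nz + 1, ny, nx)),
        Fx_dif=np.zeros((nt - 1, nz, ny, nx + 1)),
        Fy_dif=np.zeros((nt - 1, nz, ny + 1, nx)),
        Fz_dif=np.zeros((nt - 1, nz + 1, ny, nx)),
        B=np.zeros((nt - 1, nz, ny, nx)),
    )


def consistent_toy_series(seed=0, nz=4, ny=3, nx=3, dt=3600.0):
    """Small series with arbitrary ("hand-set") fluxes made exactly
    consistent by evolving the tracer with the discrete budget itself."""
    rng = np.random.default_rng(seed)
    s = quiescent_series(nz=nz, ny=ny, nx=nx, nt=2, dt=dt)
    vol = s.cell_volume(0)
    # arbitrary interior fluxes; domain boundary faces stay closed
    s.U[0][:, :, 1:-1] = rng.uniform(-1, 1, (nz, ny, nx - 1)) * 1e4
    s.V[0][:, 1:-1, :] = rng.uniform(-1, 1, (nz, ny - 1, nx)) * 1e4
    div_h = (s.U[0][:, :, :-1] - s.U[0][:, :, 1:]
             + s.V[0][:, :-1, :] - s.V[0][:, 1:, :])
    s.W[0][:-1] = np.cumsum(div_h[::-1], axis=0)[::-1]
    for F, sl in ((s.Fx_adv, (slice(None), slice(None), slice(1, -1))),
                  (s.Fy_adv, (slice(None), slice(1, -1), slice(None))),
                  (s.Fx_dif, (slice(None), slice(None), slice(1, -1))),
                  (s.Fy_dif, (slice(None), slice(1, -1), slice(None))),
                  (s.Fz_adv, (slice(1, -1), slice(None), slice(None))),
                  (s.Fz_dif, (slice(1, -1), slice(None), slice(None)))):
        F[0][sl] = rng.uniform(-1, 1, F[0][sl].shape) * 5e3
    s.B[0][:] = rng.uniform(-1, 1, (nz, ny, nx)) * 1e3
    # distinct, smooth, slightly tilted density at each instant
    z = np.cumsum(s.geom.dz) - 0.5 * s.geom.dz
    base = 23.0 + 4.5 * (z / z[-1])[:, None, None]
    tilt = 0.3 * np.linspace(0, 1, ny)[None, :, None] \
        + 0.2 * np.linspace(0, 1, nx)[None, None, :]
    s.sigma0[0] = base + tilt
    s.sigma0[1] = base + tilt * 0.7 + 0.1
    s.tracer[0] = rng.uniform(0.5, 2.0, (nz, ny, nx))
    conv = (s.Fx_adv[0][:, :, :-1] - s.Fx_adv[0][:, :, 1:]
            + s.Fx_dif[0][:, :, :-1] - s.Fx_dif[0][:, :, 1:]
            + s.Fy_adv[0][:, :-1, :] - s.Fy_adv[0][:, 1:, :]
            + s.Fy_dif[0][:, :-1, :] - s.Fy_dif[0][:, 1:, :]
            + s.Fz_adv[0][1:] - s.Fz_adv[0][:-1]
            + s.Fz_dif[0][1:] - s.Fz_dif[0][:-1])
    s.tracer[1] = s.tracer[0] + dt * (conv + s.B[0]) / vol
    return s
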