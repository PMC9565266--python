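"""Fine-grid refinement, layer assignment, conservation of the transform,
and the brute-force sub-face oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import isorelay as ir
from isorelay.density_layers import (_interp_to_fine, _refinement_plan,
                                     bin_to_layers, isopycnal_depth,
                                     refine_column)

from conftest import consistent_toy_series, quiescent_series


class TestRefineColumn:
    def test_equal_split(self):
        vals, h, parent = refine_column([50.0], [10.0], 2.0)
        np.testing.assert_allclose(h, np.full(5, 2.0))
        np.testing.assert_allclose(vals, np.full(5, 10.0))
        assert list(parent) == [0] * 5

    def test_non_divisible_cell_conserves(self):
        vals, h, _ = refine_column([7.0], [5.0], 2.0)
        assert h.size == 3
        np.testing.assert_allclose(h, np.full(3, 5.0 / 3.0))
        assert abs(vals.sum() - 7.0) < 1e-12 * 7.0

    def test_coarse_target_is_identity(self):
        vals, h, _ = refine_column([3.0, 4.0], [10.0, 20.0], 25.0)
        np.testing.assert_array_equal(vals, [3.0, 4.0])
        np.testing.assert_array_equal(h, [10.0, 20.0])

    def test_nonpositive_thickness_rejected(self):
        with pytest.raises(ir.GeometryError):
            refine_column([1.0], [0.0], 2.0)
        with pytest.raises(ir.GeometryError):
            refine_column([1.0], [5.0], -1.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.5, 500.0), min_size=1, max_size=12),
           st.floats(0.1, 50.0))
    def test_conservation_property(self, thicknesses, target_dz):
        vals = np.asarray(thicknesses) * 3.7
        fine_vals, fine_h, _ = refine_column(vals, thicknesses, target_dz)
        assert abs(fine_h.sum() - sum(thicknesses)) < 1e-9
        assert abs(fine_vals.sum() - vals.sum()) < 1e-9 * max(vals.sum(), 1)
        assert fine_h.max() <= target_dz + 1e-12


class TestAssignLayers:
    grid = ir.DensityGrid(edges=np.array([24.0, 26.0]), macro_edges=())

    def test_direct_binning(self):
        lay = ir.assign_layers(np.array([23.5, 25.0, 26.5]), self.grid)
        np.testing.assert_array_equal(lay, [0, 1, 2])

    def test_upper_closed_tie_rule(self):
        lay = ir.assign_layers(np.array([24.0]), self.grid)
        assert lay[0] == 0

    def test_inversions_sorted_before_assignment(self):
        grid = ir.DensityGrid(edges=np.array([25.0]), macro_edges=())
        lay = ir.assign_layers(np.array([25.1, 24.9]), grid)
        np.testing.assert_array_equal(lay, [0, 1])

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(22.0, 28.0), min_size=2, max_size=20))
    def test_assignment_is_vertically_monotone(self, profile):
        lay = ir.assign_layers(np.asarray(profile), self.grid)
        assert np.all(np.diff(lay) >= 0)


class TestIsopycnalDepth:
    def test_linear_profile(self):
        depth = np.linspace(0, 400, 81)
        sigma = 24.0 + (28.0 - 24.0) * depth / 400.0
        assert abs(isopycnal_depth(sigma, depth, 26.8) - 280.0) < 1e-9

    def test_outcropped_is_missing(self):
        depth = np.array([5.0, 15.0])
        assert np.isnan(isopycnal_depth(np.array([24.0, 25.0]), depth, 23.0))

    def test_denser_than_bottom_is_missing(self):
        depth = np.array([5.0, 15.0])
        assert np.isnan(isopycnal_depth(np.array([24.0, 25.0]), depth, 26.0))

    def test_two_point_midpoint(self):
        d = isopycnal_depth(np.array([26.7, 26.9]), np.array([440.0, 460.0]),
                            26.8)
        assert abs(d - 450.0) < 1e-9


def _degenerate_grid():
    """One unbounded density bin: layering must reduce to z-integration."""
    return ir.DensityGrid(edges=np.array([]), macro_edges=())


class TestBinToLayers:
    def test_single_layer_equals_z_integral(self):
        s = consistent_toy_series(seed=1)
        lf = bin_to_layers(s, 0, _degenerate_grid(), target_dz=5.0)
        assert lf.n_layers == 1
        np.testing.assert_allclose(lf.h0[0], s.geom.dz.sum(), rtol=1e-12)
        np.testing.assert_allclose(lf.content0[0], s.content(0).sum(axis=0),
                                   rtol=1e-12)
        np.testing.assert_allclose(lf.Tx_adv[0], s.Fx_adv[0].sum(axis=0),
                                   rtol=1e-12, atol=1e-9)
        np.testing.assert_allclose(lf.Vx[0], s.U[0].sum(axis=0),
                                   rtol=1e-12, atol=1e-9)
        # the diagnosed surface interface flux reproduces the input's
        # surface flux exactly; the seafloor flux is zero by construction
        np.testing.assert_allclose(lf.Wd[0], s.W[0][0], rtol=1e-9,
                                   atol=1e-9 * np.abs(s.U[0]).max())
        assert np.abs(lf.Wd[-1]).max() == 0.0
        assert np.abs(lf.Fd[-1]).max() == 0.0

    def test_steady_quiescent_has_zero_interface_fluxes(self):
        s = quiescent_series(tracer=1.0)
        grid = ir.DensityGrid(edges=np.array([24.5, 26.0]), macro_edges=())
        lf = bin_to_layers(s, 0, grid, target_dz=2.0)
        assert np.abs(lf.Fd).max() == 0.0
        assert np.abs(lf.Wd).max() == 0.0

    def test_conservation_sums(self, relay_series, relay_layered):
        """Sums over layers reproduce the z-coordinate column and face
        totals to 1e-12 relative."""
        s = relay_series
        lf = relay_layered[0]
        ocean = s.geom.ocean
        col_h = s.h[0].sum(axis=0)
        rel = np.abs(lf.h0.sum(0) - col_h)[ocean] / col_h[ocean]
        assert rel.max() < 1e-12
        col_c = s.content(0).sum(axis=0)
        rel = np.abs(lf.content0.sum(0) - col_c)[ocean] / np.abs(col_c[ocean])
        assert rel.max() < 1e-12
        for binned, total in ((lf.Tx_adv, s.Fx_adv[0]), (lf.Vx, s.U[0]),
                              (lf.Ty_adv, s.Fy_adv[0]), (lf.Vy, s.V[0])):
            scale = max(np.abs(total).max(), 1e-300)
            assert np.abs(binned.sum(0) - total.sum(0)).max() / scale < 1e-12

    def test_outcropped_layers_stay_in_arrays(self, relay_layered,
                                              density_grid):
        lf = relay_layered[0]
        assert lf.h0.shape[0] == density_grid.n_layers
        vanished = lf.h0.sum(axis=(1, 2)) == 0
        assert vanished.any()   # lightest bins outcrop somewhere
        assert np.abs(lf.Tx_adv[vanished]).max() == 0.0

    def test_inconsistent_input_raises_closure_error(self):
        s = consistent_toy_series(seed=2)
        s.B[0] += 100.0     # break the budget
        grid = ir.DensityGrid(edges=np.array([25.0]), macro_edges=())
        with pytest.raises(ir.ClosureError):
            bin_to_layers(s, 0, grid, target_dz=2.0)


# ---------------------------------------------------------------------------
# brute-force oracle: independent enumeration of every fine sub-face


def _brute_force_oracle(s, k, edges, target_dz):
    """Reference transform by explicit loops: refine each column, linearly
    interpolate sigma to sub-cell centers, sort, average across the two
    bounding instants and across the two face-adjacent columns, bin with the
    upper-closed rule, and accumulate each individual sub-face flux."""
    g = s.geom
    nz, ny, nx = g.nz, g.ny, g.nx
    nl = len(edges) + 1
    dz = s.h[k][:, 0, 0]
    n_sub = [int(np.ceil(h / target_dz)) for h in dz]
    # fine centers and parent levels
    fine_parent, fine_h, fine_c = [], [], []
    z = 0.0
    for kz in range(nz):
        hh = dz[kz] / n_sub[kz]
        for _ in range(n_sub[kz]):
            fine_parent.append(kz)
            fine_h.append(hh)
            fine_c.append(z + 0.5 * hh)
            z += hh
    zc = np.cumsum(dz) - 0.5 * dz

    def fine_sigma(t, j, i):
        prof = np.interp(fine_c, zc, s.sigma0[t][:, j, i])
        return np.sort(prof)

    def layer(sig):
        lay = 0
        for e in edges:
            if sig > e:
                lay += 1
        return lay

    Tx = np.zeros((nl, ny, nx + 1))
    for j in range(ny):
        for i in range(1, nx):
            sig = 0.5 * (
                0.5 * (fine_sigma(k, j, i - 1) + fine_sigma(k + 1, j, i - 1))
                + 0.5 * (fine_sigma(k, j, i) + fine_sigma(k + 1, j, i)))
            for f, kz in enumerate(fine_parent):
                Tx[layer(sig[f]), j, i] += s.Fx_adv[k][kz, j, i] / n_sub[kz]
    # interface tracer flux from the layer budget, seafloor up
    area = g.area

    def binned_state(t, j, i):
        sig = np.sort(np.interp(fine_c, zc, s.sigma0[t][:, j, i]))
        cont = np.zeros(nl)
        for f, kz in enumerate(fine_parent):
            c = s.tracer[t][kz, j, i] * dz[kz] * area[j, i] / n_sub[kz]
            cont[layer(sig[f])] += c
        return cont

    Ty = np.zeros((nl, ny + 1, nx))
    for j in range(1, ny):
        for i in range(nx):
            sig = 0.5 * (
                0.5 * (fine_sigma(k, j - 1, i) + fine_sigma(k + 1, j - 1, i))
                + 0.5 * (fine_sigma(k, j, i) + fine_sigma(k + 1, j, i)))
            for f, kz in enumerate(fine_parent):
                Ty[layer(sig[f]), j, i] += s.Fy_adv[k][kz, j, i] / n_sub[kz]
    return Tx, Ty, binned_state


class TestBruteForceOracle:
    def test_layer_transports_and_interface_fluxes(self):
        """3x3 columns, 4 levels, hand-set fluxes: the vectorized transform
        must agree with direct enumeration of every fine sub-face."""
        s = consistent_toy_series(seed=0)
        edges = np.array([24.8, 25.6, 26.4])
        grid = ir.DensityGrid(edges=edges, macro_edges=())
        lf = bin_to_layers(s, 0, grid, target_dz=7.0)
        Tx, Ty, binned_state = _brute_force_oracle(s, 0, edges, 7.0)
        np.testing.assert_allclose(lf.Tx_adv, Tx, rtol=1e-12, atol=1e-9)
        np.testing.assert_allclose(lf.Ty_adv, Ty, rtol=1e-12, atol=1e-9)
        # interface fluxes: independent bottom-up residual per column
        dt = s.times[1] - s.times[0]
        for j in range(3):
            for i in range(3):
                c0 = binned_state(0, j, i)
                c1 = binned_state(1, j, i)
                np.testing.assert_allclose(lf.content0[:, j, i], c0,
                                           rtol=1e-10, atol=1e-6)
                conv = (lf.Tx[:, j, i] - lf.Tx[:, j, i + 1]
                        + lf.Ty[:, j, i] - lf.Ty[:, j + 1, i])
                fd = np.zeros(len(edges) + 2)
                for l in range(len(edges), -1, -1):
                    fd[l] = fd[l + 1] + conv[l] + lf.S[l, j, i] \
                        - (c1[l] - c0[l]) / dt
                np.testing.assert_allclose(lf.Fd[:, j, i], fd,
                                           rtol=1e-9, atol=1e-6)


class TestDegenerateGridEquivalence:
    def test_whole_series_single_bin_matches_column_budget(self):
        """With one unbounded bin the layered budget is the z-column budget."""
        s = consistent_toy_series(seed=5)
        layered = ir.bin_series(s, _degenerate_grid(), target_dz=4.0)
        table = ir.layer_budget(layered)
        dt = s.times[1] - s.times[0]
        col_tend = (s.content(1).sum(0) - s.content(0).sum(0)) / dt
        np.testing.assert_allclose(table.tendency[0], col_tend,
                                   rtol=1e-9, atol=1e-6)
        np.testing.assert_allclose(table.bio[0], s.B[0].sum(0),
                                   rtol=1e-12, atol=1e-9)
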