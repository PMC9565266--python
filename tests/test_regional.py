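"""Band budgets, the gyre-interior mask, masked budgets and smoothing."""

import numpy as np
import pytest
from scipy import ndimage

import isorelay as ir

from conftest import quiescent_series


class TestBandBudget:
    def test_uniform_steady_state_has_zero_physical_terms(self):
        s = quiescent_series(nz=4, ny=8, nx=6, tracer=1.0)
        grid = ir.DensityGrid(edges=np.array([25.0]), macro_edges=(25.0,))
        layered = ir.bin_series(s, grid, target_dz=3.0)
        reyn = ir.reynolds_decompose(layered)
        table = ir.layer_budget(layered)
        region = ir.RegionSpec(lat_bounds=(10.2, 11.8))
        band = ir.band_budget(table, reyn, region)
        for col in ("physical", "dia_conv", "iso_mean_conv", "iso_eddy_conv",
                    "tendency", "bio"):
            assert np.abs(band[col].values).max() == 0.0

    def test_relay_band_sign_structure(self, relay_budget, relay_reynolds):
        """Across the subtropical band the deepest reported layer gains by
        eddy convergence while the mean flow exports (the paper's relay)."""
        band = ir.band_budget(relay_budget, relay_reynolds)
        band = band.set_index("layer")
        lower = band.loc["lower thermocline"]
        assert lower.iso_eddy_conv > 0
        assert lower.iso_mean_conv < 0
        assert band.loc["surface"].bio < 0

    def test_budget_sums_to_zero_over_all_layers(self, relay_budget,
                                                 relay_reynolds):
        band = ir.band_budget(relay_budget, relay_reynolds)
        total = (band.tendency - band.bio - band.physical).sum()
        scale = np.abs(band[["tendency", "bio", "physical"]].values).max()
        assert abs(total) < 1e-9 * scale

    def test_boundary_fluxes_account_for_iso_convergence(self, relay_budget,
                                                         relay_reynolds):
        band = ir.band_budget(relay_budget, relay_reynolds)
        lhs = band.iso_mean_conv + band.iso_eddy_conv
        rhs = (band.south_mean_in + band.north_mean_in
               + band.south_eddy_in + band.north_eddy_in)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9,
                                   atol=1e-9 * np.abs(lhs).max())

    def test_band_not_zonally_closed_names_columns(self, relay_budget,
                                                   relay_reynolds):
        region = ir.RegionSpec(lat_bounds=(12.0, 42.0),
                               lon_bounds=(150.0, 170.0))
        with pytest.raises(ir.RegionError, match="not zonally closed"):
            ir.band_budget(relay_budget, relay_reynolds, region)

    def test_empty_band_rejected(self, relay_budget, relay_reynolds):
        with pytest.raises(ir.RegionError):
            ir.band_budget(relay_budget, relay_reynolds,
                           ir.RegionSpec(lat_bounds=(80.0, 81.0)))


class TestGyreInteriorMask:
    def test_flat_deep_stratification_is_all_true(self):
        # sigma0 = 26.8 sits near 620 m everywhere, deeper than 450 m
        s = quiescent_series(nz=4, ny=5, nx=5, sigma_span=(23.0, 27.4),
                             dz=np.full(4, 200.0))
        mask = ir.gyre_interior_mask(s)
        assert mask.all()

    def test_threshold_is_strict(self, relay_series):
        """Columns whose isopycnal depth equals the threshold are excluded."""
        mask450 = ir.gyre_interior_mask(
            relay_series, ir.RegionSpec(kind="isopycnal_depth_mask",
                                        depth_threshold=450.0))
        # strictness: a threshold equal to the exact depth of some column
        # cannot include that column
        from isorelay.density_layers import (_interp_to_fine,
                                             _refinement_plan,
                                             _uniform_profile, isopycnal_depth)
        prof = _uniform_profile(relay_series.h[0], relay_series.geom.ocean)
        plan = _refinement_plan(prof, 2.0)
        depth = isopycnal_depth(
            _interp_to_fine(relay_series.sigma0.mean(axis=0), plan),
            plan.fine_center, 26.8)
        j, i = np.unravel_index(np.nanargmax(np.where(mask450, depth, np.nan)),
                                depth.shape)
        exact = float(depth[j, i])
        mask_exact = ir.gyre_interior_mask(
            relay_series, ir.RegionSpec(kind="isopycnal_depth_mask",
                                        depth_threshold=exact))
        assert not mask_exact[j, i]

    def test_deeper_threshold_shrinks_mask(self, relay_series):
        masks = [ir.gyre_interior_mask(
            relay_series, ir.RegionSpec(kind="isopycnal_depth_mask",
                                        depth_threshold=d))
            for d in (420.0, 450.0, 500.0)]
        assert masks[0].sum() >= masks[1].sum() >= masks[2].sum()
        assert (masks[1] & ~masks[0]).sum() == 0    # nested


class TestMaskedBudget:
    def test_whole_band_mask_matches_band_budget(self, relay_series,
                                                 relay_budget, relay_reynolds):
        geom = relay_series.geom
        rows = (geom.lat > 12.0) & (geom.lat < 42.0)
        mask = np.zeros_like(geom.land_mask)
        mask[rows, :] = True
        band = ir.band_budget(relay_budget, relay_reynolds).set_index("layer")
        sub = ir.masked_budget(relay_budget, relay_reynolds,
                               mask).set_index("layer")
        for col in ("bio", "tendency", "dia_conv", "iso_mean_conv",
                    "iso_eddy_conv"):
            np.testing.assert_allclose(sub[col], band[col], rtol=1e-10,
                                       atol=1e-10 * np.abs(band[col]).max())

    def test_complementary_masks_are_additive(self, relay_series,
                                              relay_budget, relay_reynolds,
                                              interior_mask):
        whole = np.ones_like(interior_mask)
        comp = whole & ~interior_mask
        a = ir.masked_budget(relay_budget, relay_reynolds, interior_mask)
        b = ir.masked_budget(relay_budget, relay_reynolds, comp)
        w = ir.masked_budget(relay_budget, relay_reynolds, whole)
        for col in ("bio", "tendency", "dia_conv"):
            np.testing.assert_allclose(a[col] + b[col], w[col], rtol=1e-10,
                                       atol=1e-10 * np.abs(w[col]).max())

    def test_relay_interior_eddy_convergence_positive_all_layers(
            self, relay_budget, relay_reynolds, interior_mask):
        t = ir.masked_budget(relay_budget, relay_reynolds,
                             interior_mask).set_index("layer")
        for layer in ("surface", "upper thermocline", "lower thermocline"):
            assert t.loc[layer].iso_eddy_conv > 0

    def test_empty_mask_rejected(self, relay_budget, relay_reynolds):
        with pytest.raises(ir.RegionError):
            ir.masked_budget(relay_budget, relay_reynolds,
                             np.zeros((40, 40), bool))


class TestSmoothGaussian:
    def test_constant_field_unchanged(self):
        land = np.zeros((20, 20), bool)
        land[:5, :5] = True
        field = np.full((20, 20), 3.3)
        out = ir.smooth_gaussian(field, land, sd_gridpoints=1.0)
        np.testing.assert_allclose(out[~land], 3.3, rtol=1e-12)

    def test_unit_spike_center_matches_kernel(self):
        """Spike response center equals the discrete normalized kernel's
        center weight, computed independently from the 1-D kernel."""
        n = 31
        field = np.zeros((n, n))
        field[n // 2, n // 2] = 1.0
        out = ir.smooth_gaussian(field, None, sd_gridpoints=1.0)
        # independent oracle: separable discrete Gaussian, truncated at 4 SD
        r = 4
        x = np.arange(-r, r + 1)
        k1 = np.exp(-0.5 * x ** 2)
        k1 /= k1.sum()
        expected_center = float(k1[r] * k1[r])
        assert abs(out[n // 2, n // 2] - expected_center) < 1e-6

    def test_zero_sd_is_identity(self):
        rng = np.random.default_rng(0)
        field = rng.normal(size=(8, 8))
        np.testing.assert_array_equal(ir.smooth_gaussian(field, None, 0.0),
                                      field)

    def test_interior_integral_preserved_to_truncation(self):
        # a spike far from any boundary keeps its integral up to the mass
        # cut off beyond 4 SD
        n = 31
        field = np.zeros((n, n))
        field[n // 2, n // 2] = 7.0
        out = ir.smooth_gaussian(field, None, sd_gridpoints=1.0)
        assert abs(out.sum() - 7.0) < 1e-4
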