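"""Voxelwise SPR conversion, ROI statistics, overrides and the hypothetical CT."""

import numpy as np
import pytest

from porospr.convert import (
    AIR_RHO_E_THRESHOLD,
    RoiCylinder,
    deedz_spr_map,
    delta_spr_map,
    mask_statistics,
    override_spr_region,
    roi_cylinder_mean,
    scatter_samples,
    sect_spr_map,
    spr_to_hypothetical_ct,
)
from porospr.dect import default_params
from porospr.physics import PhysicsConstants, stopping_number_denominator
from porospr.sect import SectLut
from porospr.volumes import SprVolume, VoxelVolume


def _vol(data, tube="120kV"):
    return VoxelVolume(data=np.asarray(data, dtype=float), spacing=(1.0, 1.0, 1.0), tube=tube)


def _spr(data, provenance="truth"):
    return SprVolume(data=np.asarray(data, dtype=float), spacing=(1.0, 1.0, 1.0),
                     provenance=provenance)


SIMPLE_LUT = SectLut(
    hu=np.array([-1000.0, 0.0, 1000.0, 2000.0]),
    spr=np.array([0.0, 1.0, 1.6, 2.1]),
)


class TestDeedzMap:
    def test_water_voxel_published_constants(self, beam):
        """HU pair (0, 0) with the published set: rho_e 1.00, soft branch,
        ln(I/I_w) = -0.0206, SPR = 1 + 0.0206/denominator ~ 1.0025."""
        params = default_params()
        constants = PhysicsConstants(i_water=75.3)
        zeros = np.zeros((2, 2, 2))
        spr, inter = deedz_spr_map(_vol(zeros, "80kV"), _vol(zeros, "135kV"), params, beam,
                                   constants)
        assert np.allclose(inter.rho_e, 1.0, atol=1e-12)
        assert np.allclose(inter.x, 0.0, atol=1e-12)
        assert np.all(inter.branch == "soft")
        assert np.allclose(inter.ln_i_ratio, -0.0206, atol=1e-12)
        denom = stopping_number_denominator(beam.beta, constants)
        assert np.allclose(spr.data, 1.0 + 0.0206 / denom, atol=1e-12)
        assert spr.data[0, 0, 0] == pytest.approx(1.00255, abs=1e-4)

    def test_rho_e_at_1000_1000(self, beam):
        params = default_params()
        ones = np.full((1, 1, 1), 1000.0)
        _, inter = deedz_spr_map(_vol(ones, "80kV"), _vol(ones, "135kV"), params, beam)
        # a ((1+alpha) 1000 - alpha 1000)/1000 + b = 1.01 + 1.00
        assert inter.rho_e[0, 0, 0] == pytest.approx(2.01, abs=1e-12)

    def test_air_voxels_get_zero_spr(self, beam):
        params = default_params()
        air = np.full((2, 2, 2), -1000.0)
        spr, inter = deedz_spr_map(_vol(air, "80kV"), _vol(air, "135kV"), params, beam)
        assert np.all(spr.data == 0.0)
        assert np.all(inter.branch == "air")
        assert np.all(inter.rho_e < AIR_RHO_E_THRESHOLD)

    def test_branch_covers_every_voxel(self, beam):
        rng = np.random.default_rng(3)
        hu_l = rng.uniform(-1000, 1800, size=(6, 6, 6))
        hu_h = rng.uniform(-1000, 1800, size=(6, 6, 6))
        _, inter = deedz_spr_map(_vol(hu_l, "80kV"), _vol(hu_h, "135kV"),
                                 default_params(), beam)
        assert set(np.unique(inter.branch)) <= {"soft", "bone", "air"}

    def test_matches_scalar_reference(self, beam):
        """Vectorized chain equals a per-voxel scalar transcription to 1e-12."""
        import math

        params = default_params()
        constants = PhysicsConstants().with_m(params.m)
        rng = np.random.default_rng(42)
        hu_l = rng.uniform(-1000.0, 1800.0, size=(16, 16, 16))
        hu_h = rng.uniform(-1000.0, 1800.0, size=(16, 16, 16))
        spr, _ = deedz_spr_map(_vol(hu_l, "80kV"), _vol(hu_h, "135kV"), params, beam, constants)

        denom = math.log(
            2 * constants.me_c2 * beam.beta**2 / (constants.i_water * (1 - beam.beta**2))
        ) - beam.beta**2
        x_star = (params.ean_split / constants.zeff_water) ** params.m - 1.0
        expected = np.empty_like(hu_l)
        for idx in np.ndindex(hu_l.shape):
            l, h = hu_l[idx], hu_h[idx]
            rho = params.a * ((1 + params.alpha) * h - params.alpha * l) / 1000.0 + params.b
            if rho < AIR_RHO_E_THRESHOLD:
                expected[idx] = 0.0
                continue
            x = max(params.gamma_L * ((l / 1000.0 + 1.0) / rho - 1.0), -1.0 + 1e-9)
            if x >= x_star:
                ln_ratio = params.c1_bone * x - params.c0_bone
            else:
                ln_ratio = params.c1_soft * x - params.c0_soft
            expected[idx] = max(rho * (1.0 - ln_ratio / denom), 0.0)
        assert np.max(np.abs(spr.data - expected)) <= 1e-12

    def test_shape_mismatch_rejected(self, beam):
        with pytest.raises(ValueError, match="misaligned"):
            deedz_spr_map(_vol(np.zeros((2, 2, 2))), _vol(np.zeros((3, 3, 3))),
                          default_params(), beam)


class TestSectMap:
    def test_zero_hu_maps_to_unity(self):
        spr = sect_spr_map(_vol(np.zeros((3, 3, 3))), SIMPLE_LUT)
        assert np.all(spr.data == 1.0)
        assert spr.provenance == "SECT"

    def test_node_values_are_exact(self):
        vol = _vol(np.array(SIMPLE_LUT.hu).reshape(4, 1, 1))
        spr = sect_spr_map(vol, SIMPLE_LUT)
        assert np.allclose(spr.data.ravel(), SIMPLE_LUT.spr, atol=1e-12)

    def test_vectorized_equals_scalar_lookup(self):
        rng = np.random.default_rng(7)
        hu = rng.uniform(-1200, 2500, size=(8, 8, 4))
        spr = sect_spr_map(_vol(hu), SIMPLE_LUT)
        for idx in np.ndindex(hu.shape):
            assert spr.data[idx] == pytest.approx(SIMPLE_LUT.lookup(float(hu[idx])), abs=1e-12)


class TestDeltaAndStats:
    def test_delta_antisymmetry(self):
        a = _spr(np.full((2, 2, 2), 1.0), "DECT")
        b = _spr(np.full((2, 2, 2), 1.1), "SECT")
        assert np.allclose(delta_spr_map(a, b), -0.1, atol=1e-12)
        assert np.allclose(delta_spr_map(b, a), -delta_spr_map(a, b))
        assert np.allclose(delta_spr_map(a, a), 0.0)

    def test_misaligned_delta_rejected(self):
        a = _spr(np.ones((2, 2, 2)))
        b = SprVolume(data=np.ones((2, 2, 2)), spacing=(2.0, 2.0, 2.0))
        with pytest.raises(ValueError):
            delta_spr_map(a, b)

    def test_mask_median_and_histogram(self):
        data = np.zeros((3, 1, 1))
        data[:, 0, 0] = [1.0, 2.0, 3.0]
        spr = _spr(data)
        stats = mask_statistics(spr, np.ones((3, 1, 1), dtype=bool),
                                bin_edges=np.array([0.0, 1.5, 2.5, 3.5]))
        assert stats["median"] == 2.0
        assert list(stats["counts"]) == [1, 1, 1]

    def test_constant_region_single_bin(self):
        spr = _spr(np.full((4, 4, 4), 1.2))
        stats = mask_statistics(spr, np.ones((4, 4, 4), dtype=bool))
        assert (stats["counts"] > 0).sum() == 1
        assert stats["median"] == pytest.approx(1.2)

    def test_relative_median_difference_definition(self):
        base = np.full((3, 3, 3), 1.5)
        a = _spr(0.927 * base, "DECT")
        b = _spr(base, "SECT")
        sa = mask_statistics(a, np.ones_like(base, dtype=bool))
        sb = mask_statistics(b, np.ones_like(base, dtype=bool))
        shift = 100.0 * (sa["median"] - sb["median"]) / sb["median"]
        assert shift == pytest.approx(-7.3, abs=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mask_statistics(_spr(np.ones((2, 2, 2))), np.zeros((2, 2, 2), dtype=bool))

    def test_scatter_pairs(self):
        a = _spr(np.full((2, 2, 2), 1.0), "SECT")
        b = _spr(np.full((2, 2, 2), 1.2), "DECT")
        df = scatter_samples(a, b, np.ones((2, 2, 2), dtype=bool))
        assert len(df) == 8
        assert np.allclose(df["delta_spr"], 0.2)


class TestRoi:
    def test_constant_volume_any_roi(self):
        spr = _spr(np.full((20, 20, 20), 1.7))
        mean, n = roi_cylinder_mean(spr, RoiCylinder(center=(10.0, 10.0, 10.0)))
        assert mean == pytest.approx(1.7)
        assert n > 0

    def test_half_and_half_split(self):
        data = np.full((21, 21, 21), 1.0)
        data[:, 11:, :] = 2.0  # split across the ROI axis (y)
        spr = _spr(data)
        roi = RoiCylinder(center=(10.0, 10.5, 10.0), diameter=6.0, length=10.0)
        mean, n = roi_cylinder_mean(spr, roi)
        assert mean == pytest.approx(1.5, abs=0.5 / n * 10)

    def test_outside_grid_rejected(self):
        spr = _spr(np.ones((5, 5, 5)))
        with pytest.raises(ValueError, match="no voxel"):
            roi_cylinder_mean(spr, RoiCylinder(center=(100.0, 100.0, 100.0)))


class TestOverride:
    def test_full_override_uniform(self):
        spr = _spr(np.linspace(0.5, 2.0, 8).reshape(2, 2, 2))
        out = override_spr_region(spr, np.ones((2, 2, 2), dtype=bool), 1.0)
        assert np.all(out.data == 1.0)
        assert not np.all(spr.data == 1.0)  # input untouched

    def test_empty_mask_is_identity(self):
        spr = _spr(np.linspace(0.5, 2.0, 8).reshape(2, 2, 2))
        out = override_spr_region(spr, np.zeros((2, 2, 2), dtype=bool), 1.0)
        assert np.array_equal(out.data, spr.data)

    def test_override_then_stats(self):
        spr = _spr(np.linspace(0.5, 2.0, 27).reshape(3, 3, 3))
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1] = True
        out = override_spr_region(spr, mask, 1.0)
        assert mask_statistics(out, mask)["median"] == 1.0

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            override_spr_region(_spr(np.ones((2, 2, 2))), np.ones((2, 2, 2), dtype=bool), -1.0)


class TestHypotheticalCt:
    def test_uniform_water_spr_gives_zero_hu(self):
        spr = _spr(np.ones((3, 3, 3)), "DECT")
        ct = spr_to_hypothetical_ct(spr, SIMPLE_LUT)
        assert np.allclose(ct.data, 0.0, atol=1e-9)
        assert ct.meta["hypothetical"] is True
        assert ct.tube == "120kV"

    def test_zero_spr_gives_air_hu(self):
        spr = _spr(np.zeros((2, 2, 2)), "DECT")
        ct = spr_to_hypothetical_ct(spr, SIMPLE_LUT)
        assert np.allclose(ct.data, -1000.0, atol=1e-9)

    def test_round_trip(self):
        rng = np.random.default_rng(5)
        spr = _spr(rng.uniform(0.0, 2.0, size=(8, 8, 4)), "DECT")
        ct = spr_to_hypothetical_ct(spr, SIMPLE_LUT)
        back = sect_spr_map(ct, SIMPLE_LUT)
        assert np.max(np.abs(back.data - spr.data)) <= 1e-6
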