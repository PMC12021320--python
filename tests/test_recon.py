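"""Two-pass combination, spatial averaging, reconstruction and ROIs."""

import numpy as np
import pytest

from pbr2 import (
    ComplexVolume,
    EmptyROIError,
    ROISpec,
    combine_two_pass,
    reconstruct_r2,
    roi_stats,
    spatial_average,
)
from pbr2.engine import signal_phase, simulate_signals
from pbr2.recon import read_complex_nifti, write_complex_nifti


def _pair_from_signal(zp, shape=(12, 12, 3), voxel=(4.8, 4.8, 10.0), seq=None):
    plus = ComplexVolume(np.full(shape, zp), voxel, +1, seq)
    minus = ComplexVolume(np.full(shape, np.conj(zp)), voxel, -1, seq)
    return plus, minus


class TestCombineTwoPass:
    def test_common_phase_field_cancels(self, seq3, sim_config):
        z = simulate_signals(seq3, 1.0, 150.0, sim_config)[0]
        plus, minus = _pair_from_signal(z)
        rng = np.random.default_rng(0)
        bg = np.exp(1j * rng.uniform(-np.pi, np.pi, plus.data.shape))
        plus_bg = ComplexVolume(plus.data * bg, plus.voxel_size, +1)
        minus_bg = ComplexVolume(minus.data * bg, minus.voxel_size, -1)
        a = combine_two_pass(plus, minus)
        b = combine_two_pass(plus_bg, minus_bg)
        np.testing.assert_allclose(b.phase_deg, a.phase_deg, atol=1e-10)

    def test_noiseless_phase_matches_simulation(self, seq3, sim_config):
        z = simulate_signals(seq3, 1.0, 120.0, sim_config)[0]
        plus, minus = _pair_from_signal(z)
        out = combine_two_pass(plus, minus)
        expected = float(signal_phase(z))
        np.testing.assert_allclose(out.phase_deg, expected, atol=1e-6)

    def test_conjugate_pair_reproduces_plus_phase(self):
        zp = 0.02 + 0.01j
        plus, minus = _pair_from_signal(zp)
        out = combine_two_pass(plus, minus)
        np.testing.assert_allclose(
            out.phase_deg, np.degrees(np.angle(zp)), atol=1e-10
        )

    def test_dimension_mismatch_rejected(self):
        plus, _ = _pair_from_signal(1 + 1j, shape=(8, 8, 2))
        _, minus = _pair_from_signal(1 + 1j, shape=(9, 8, 2))
        with pytest.raises(ValueError):
            combine_two_pass(plus, minus)

    def test_sign_mismatch_rejected(self):
        plus, _ = _pair_from_signal(1 + 1j)
        plus2, _ = _pair_from_signal(1 + 1j)
        with pytest.raises(ValueError):
            combine_two_pass(plus, plus2)


class TestSpatialAverage:
    def test_constant_volume_is_fixed_point(self):
        vol = ComplexVolume(np.full((10, 10, 2), 0.3 - 0.2j), (4.8, 4.8, 10.0), +1)
        out = spatial_average(vol, 3)
        np.testing.assert_allclose(out.data, vol.data, atol=1e-14)

    def test_kernel_one_is_identity(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((6, 6, 2)) + 1j * rng.standard_normal((6, 6, 2))
        vol = ComplexVolume(data, (4.8, 4.8, 10.0), +1)
        np.testing.assert_array_equal(spatial_average(vol, 1).data, data)

    def test_even_kernel_rejected(self):
        vol = ComplexVolume(np.ones((4, 4, 1), complex), (1, 1, 1), +1)
        with pytest.raises(ValueError):
            spatial_average(vol, 2)

    def test_averaging_is_in_plane_only(self):
        data = np.zeros((5, 5, 3), complex)
        data[:, :, 1] = 1.0
        vol = ComplexVolume(data, (1, 1, 1), +1)
        out = spatial_average(vol, 3)
        assert np.all(out.data[:, :, 0] == 0)  # no bleed across slices

    def test_averaging_reduces_negative_phase_fraction(self, seq3, sim_config):
        """Noisy high-R2 voxels: complex averaging pulls phases positive."""
        z = simulate_signals(seq3.with_(tr=9.0), 1.0, 150.0, sim_config)[0]
        rng = np.random.default_rng(5)
        shape = (60, 60, 2)
        sigma = abs(z) / 20.0
        noisy = z + sigma * (
            rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        )
        vol = ComplexVolume(noisy, (4.8, 4.8, 10.0), +1)
        frac_before = np.mean(np.degrees(np.angle(vol.data)) < 0)
        frac_after = np.mean(np.degrees(np.angle(spatial_average(vol, 3).data)) < 0)
        assert frac_before > 0
        assert frac_after < frac_before


class TestReconstructR2:
    def test_noiseless_round_trip(self, seq3, lut_tr3_wide, sim_config):
        z = simulate_signals(seq3, 1.0, 180.0, sim_config)[0]
        plus, minus = _pair_from_signal(z, seq=seq3)
        minus.seq = seq3.with_(phase_increment=-2.0)
        r2_map, r1_map = reconstruct_r2(plus, minus, lut_tr3_wide, kernel_size=3)
        assert r1_map is None
        assert np.nanmedian(r2_map.masked()) == pytest.approx(
            180.0, abs=lut_tr3_wide.grid_step
        )

    def test_mismatched_lut_rejected(self, seq3, lut_tr3_wide):
        other = seq3.with_(tr=6.0)
        plus, minus = _pair_from_signal(0.01 + 0.02j, seq=other)
        minus.seq = other.with_(phase_increment=-2.0)
        with pytest.raises(ValueError, match="different sequence"):
            reconstruct_r2(plus, minus, lut_tr3_wide)

    def test_all_zero_volumes_fully_masked(self, lut_tr3_wide):
        plus = ComplexVolume(np.zeros((8, 8, 2), complex), (4.8, 4.8, 10.0), +1)
        minus = ComplexVolume(np.zeros((8, 8, 2), complex), (4.8, 4.8, 10.0), -1)
        r2_map, _ = reconstruct_r2(plus, minus, lut_tr3_wide, kernel_size=1)
        assert not r2_map.mask.any()

    def test_provenance_reports_effective_footprint(self, seq3, lut_tr3_wide):
        plus, minus = _pair_from_signal(0.01 + 0.02j)
        r2_map, _ = reconstruct_r2(plus, minus, lut_tr3_wide, kernel_size=3)
        assert r2_map.provenance["effective_inplane_footprint_mm"] == [
            3 * 4.8,
            3 * 4.8,
        ]


class TestRoiStats:
    def test_uniform_map_statistics(self, lut_tr3_wide):
        plus, minus = _pair_from_signal(0.01 + 0.02j, shape=(20, 20, 3))
        r2_map, _ = reconstruct_r2(plus, minus, lut_tr3_wide, kernel_size=1)
        roi = ROISpec(center=(10, 10), slice_index=1, area_cm2=2.0)
        st = roi_stats(r2_map, roi)
        assert st.sd == pytest.approx(0.0, abs=1e-9)
        assert st.mean == pytest.approx(float(r2_map.values[10, 10, 1]))

    def test_two_cm2_roi_voxel_count(self):
        """2 cm^2 circle at 4.8 mm pitch rasterizes to 8-9 voxel centers."""
        roi = ROISpec(center=(10, 10), slice_index=0, area_cm2=2.0)
        m = roi.rasterize((20, 20, 1), (4.8, 4.8, 10.0))
        assert 8 <= m.sum() <= 9

    def test_fully_masked_roi_raises(self, lut_tr3_wide):
        plus = ComplexVolume(np.zeros((20, 20, 1), complex), (4.8, 4.8, 10.0), +1)
        minus = ComplexVolume(np.zeros((20, 20, 1), complex), (4.8, 4.8, 10.0), -1)
        r2_map, _ = reconstruct_r2(plus, minus, lut_tr3_wide, kernel_size=1)
        with pytest.raises(EmptyROIError):
            roi_stats(r2_map, ROISpec(center=(10, 10), slice_index=0, area_cm2=2.0))


class TestNiftiIO:
    @pytest.mark.parametrize("dialect", ["real_imag", "mag_phase"])
    def test_roundtrip(self, tmp_path, dialect):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((6, 5, 4)) + 1j * rng.standard_normal((6, 5, 4))
        vol = ComplexVolume(data, (4.8, 4.8, 10.0), +1)
        write_complex_nifti(vol, tmp_path / "vol", dialect)
        back = read_complex_nifti(tmp_path / "vol", +1, dialect)
        np.testing.assert_allclose(back.data, data, atol=1e-6)
        assert back.voxel_size == pytest.approx(vol.voxel_size)
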