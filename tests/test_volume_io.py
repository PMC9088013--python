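"""Volume I/O, preprocessing chain, and slice decomposition."""

from __future__ import annotations

import numpy as np
import pytest

from msa3d import (EmptyForegroundError, Volume, VolumeFormatError,
                   crop_background, extract_slices, normalize_intensity,
                   preprocess, read_volume, resize_volume, stack_slices,
                   write_volume)

RNG = np.random.default_rng(42)


class TestNiftiIO:
    def test_round_trip_identity(self, tmp_path):
        v = Volume(RNG.standard_normal((8, 9, 10)), spacing=(2.0, 2.0, 2.0))
        p = write_volume(v, tmp_path / "v.nii.gz")
        back = read_volume(p)
        np.testing.assert_allclose(back.data, v.data, rtol=1e-6)
        assert back.spacing == pytest.approx(v.spacing)

    def test_model_grid_shape_preserved(self, tmp_path):
        """The standard 2 mm model grid reads back as (91, 101, 91)."""
        v = Volume(np.zeros((91, 101, 91), dtype=np.float32))
        p = write_volume(v, tmp_path / "grid.nii.gz")
        assert read_volume(p).shape == (91, 101, 91)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "absent.nii")

    def test_non_nifti_content(self, tmp_path):
        bad = tmp_path / "fake.nii"
        bad.write_text("this is not a nifti header")
        with pytest.raises(VolumeFormatError):
            read_volume(bad)


class TestCrop:
    def test_bounding_box_identity(self):
        cube = np.zeros((11, 11, 11))
        cube[3:8, 3:8, 3:8] = 1.0
        out = crop_background(Volume(cube), 0.0)
        assert out.shape == (5, 5, 5)
        np.testing.assert_array_equal(out.data, np.ones((5, 5, 5)))

    def test_no_background_unchanged(self):
        v = Volume(np.full((4, 5, 6), 2.0))
        out = crop_background(v, 0.0)
        np.testing.assert_array_equal(out.data, v.data)

    def test_empty_foreground_error(self):
        with pytest.raises(EmptyForegroundError):
            crop_background(Volume(np.zeros((3, 3, 3))), 0.0)

    def test_idempotent(self):
        data = np.zeros((9, 8, 7))
        data[2:5, 1:6, 3:5] = RNG.random((3, 5, 2)) + 0.5
        once = crop_background(Volume(data), 0.0)
        twice = crop_background(once, 0.0)
        np.testing.assert_array_equal(once.data, twice.data)


class TestNormalize:
    def test_constant_maps_to_zero(self):
        out = normalize_intensity(Volume(np.full((4, 4, 4), 7.0)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_zero_mean_unit_sd(self):
        out = normalize_intensity(Volume(RNG.random((6, 7, 8))))
        assert abs(out.data.mean()) < 1e-6
        assert abs(out.data.std() - 1) < 1e-6

    def test_affine_invariance(self):
        data = RNG.random((5, 6, 7))
        a = normalize_intensity(Volume(data))
        b = normalize_intensity(Volume(3.5 * data - 2.0))
        np.testing.assert_allclose(a.data, b.data, atol=1e-6)

    def test_idempotent(self):
        v = normalize_intensity(Volume(RNG.random((5, 5, 5))))
        again = normalize_intensity(v)
        np.testing.assert_allclose(v.data, again.data, atol=1e-6)


class TestResize:
    def test_identity(self):
        v = Volume(RNG.random((6, 7, 8)))
        out = resize_volume(v, (6, 7, 8))
        np.testing.assert_allclose(out.data, v.data, atol=1e-6)

    def test_constant_preserved(self):
        out = resize_volume(Volume(np.full((4, 4, 4), 3.3)), (9, 5, 7))
        np.testing.assert_allclose(out.data, 3.3, atol=1e-6)

    def test_linear_ramp_matches_closed_form(self):
        """2x upsampling of a ramp equals the exact linear interpolant."""
        n = 6
        ramp = np.broadcast_to(np.arange(n, dtype=float)[:, None, None],
                               (n, 4, 4)).copy()
        out = resize_volume(Volume(ramp), (2 * n, 4, 4))
        # align-corners: output i sits at input coordinate i*(n-1)/(2n-1)
        coords = np.arange(2 * n) * (n - 1) / (2 * n - 1)
        expected = np.broadcast_to(coords[:, None, None], (2 * n, 4, 4))
        np.testing.assert_allclose(out.data, expected, atol=1e-6)

    def test_round_trip_constant_exact(self):
        v = Volume(np.full((5, 5, 5), 1.5))
        back = resize_volume(resize_volume(v, (8, 9, 10)), (5, 5, 5))
        np.testing.assert_allclose(back.data, v.data, atol=1e-12)

    def test_bad_target(self):
        with pytest.raises(ValueError):
            resize_volume(Volume(np.zeros((3, 3, 3))), (0, 3, 3))


class TestSlices:
    def test_counts_match_grid(self):
        bank = extract_slices(Volume(np.zeros((91, 101, 91), dtype=np.float32)))
        assert bank.counts == (91, 101, 91)

    @pytest.mark.parametrize("view,axis", [("sagittal", 0), ("coronal", 1),
                                           ("axial", 2)])
    def test_restack_is_identity(self, view, axis):
        v = Volume(RNG.random((5, 6, 7)))
        bank = extract_slices(v)
        back = stack_slices(bank.view(view), view)
        np.testing.assert_array_equal(back.data, v.data)

    def test_degenerate_single_voxel(self):
        bank = extract_slices(Volume(np.ones((1, 1, 1))))
        assert bank.counts == (1, 1, 1)
        assert bank.sagittal[0].shape == (1, 1)


def test_preprocess_chain_and_config(tmp_path):
    data = np.zeros((20, 22, 20))
    data[4:16, 5:17, 4:16] = 1.0 + RNG.random((12, 12, 12))
    v = Volume(data)
    out = preprocess(v, target_grid=(10, 11, 10))
    assert out.shape == (10, 11, 10)
    assert out.is_finite()
    from msa3d.volume_io import preprocess_config
    cfg = tmp_path / "prep.yaml"
    cfg.write_text("crop: true\nnormalize: true\ntarget_grid: [10, 11, 10]\n")
    out2 = preprocess_config(cfg)(v)
    np.testing.assert_allclose(out.data, out2.data)
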