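"""Stack I/O, channel alignment, binning, background, normalization."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fretmask as fm
from fretmask.stacks import save_rois
from conftest import noise_free


class TestRoiPolygon:
    def test_requires_three_vertices(self):
        with pytest.raises(fm.ConfigError):
            fm.RoiPolygon(((0, 0), (5, 5)))

    def test_rejects_self_intersection(self):
        bowtie = ((0, 0), (10, 10), (10, 0), (0, 10))
        with pytest.raises(fm.ConfigError):
            fm.RoiPolygon(bowtie)

    def test_rectangle_mask_pixel_centers(self):
        roi = fm.RoiPolygon.rectangle(1, 1, 4, 3)
        m = roi.mask((6, 6))
        rows, cols = np.nonzero(m)
        assert rows.min() >= 1 and rows.max() <= 3
        assert cols.min() >= 1 and cols.max() <= 4

    def test_out_of_bounds_rejected(self):
        roi = fm.RoiPolygon.rectangle(0, 0, 100, 100)
        with pytest.raises(fm.ConfigError):
            roi.mask((10, 10))

    def test_json_round_trip(self, tmp_path):
        rois = {"vessel": fm.RoiPolygon.rectangle(2, 3, 8, 9, "vessel"),
                "background": fm.RoiPolygon.rectangle(0, 0, 3, 3, "background")}
        path = tmp_path / "rois.json"
        save_rois(rois, path)
        loaded = fm.load_rois(path)
        assert set(loaded) == {"vessel", "background"}
        assert loaded["vessel"].vertices == rois["vessel"].vertices

    def test_load_accepts_wrapper_dict(self, tmp_path):
        path = tmp_path / "r.json"
        path.write_text(json.dumps(
            {"rois": [{"label": "a", "vertices": [[0, 0], [4, 0], [4, 4]]}]}))
        assert "a" in fm.load_rois(path)


class TestStackIO:
    def test_uint16_round_trip_bit_identical(self, tmp_path, rng):
        arr = rng.integers(0, 65535, (4, 8, 10), dtype=np.uint16)
        stack = fm.TwoChannelStack(arr, arr[::-1].copy(), 2.0)
        fm.write_stack(stack, tmp_path / "d.tif", tmp_path / "a.tif")
        back = fm.read_stack(tmp_path / "d.tif", tmp_path / "a.tif", 2.0)
        np.testing.assert_array_equal(back.donor, arr)
        np.testing.assert_array_equal(back.acceptor, arr[::-1])

    def test_float_nan_round_trip(self, tmp_path):
        arr = np.ones((2, 4, 4))
        arr[0, 0, 0] = np.nan
        stack = fm.TwoChannelStack(arr, arr.copy())
        fm.write_stack(stack, tmp_path / "d.tif", tmp_path / "a.tif")
        back = fm.read_stack(tmp_path / "d.tif", tmp_path / "a.tif")
        assert np.isnan(back.donor[0, 0, 0])

    def test_unequal_frame_counts_rejected(self, tmp_path):
        import tifffile
        tifffile.imwrite(tmp_path / "d.tif", np.zeros((3, 4, 4), np.uint16))
        tifffile.imwrite(tmp_path / "a.tif", np.zeros((2, 4, 4), np.uint16))
        with pytest.raises(fm.DataError):
            fm.read_stack(tmp_path / "d.tif", tmp_path / "a.tif")

    def test_shape_mismatch_rejected_in_memory(self):
        with pytest.raises(fm.DataError):
            fm.TwoChannelStack(np.zeros((2, 4, 4)), np.zeros((2, 4, 5)))


class TestAlignChannels:
    # a striated patch breaks the vertical vessel's translational symmetry
    # along y, making the 2-D shift identifiable
    PATCH = ((2, 2, 7, 11),)

    def test_recovers_phantom_misalignment(self):
        cfg = noise_free(n_frames=6, channel_misalignment=(3, -2),
                         striated_patches=self.PATCH)
        stack, _ = fm.simulate_timelapse(cfg)
        aligned, shift = fm.align_channels(stack, max_shift=5)
        assert shift == (-3, 2)       # inverse of the imposed (3, -2)
        ref, _ = fm.simulate_timelapse(
            noise_free(n_frames=6, striated_patches=self.PATCH))
        np.testing.assert_array_equal(aligned.acceptor, ref.acceptor)

    def test_aligned_stack_reports_zero_shift(self):
        cfg = noise_free(n_frames=4, striated_patches=self.PATCH)
        stack, _ = fm.simulate_timelapse(cfg)
        _, shift = fm.align_channels(stack, max_shift=4)
        assert shift == (0, 0)

    def test_manual_shift_applied_verbatim(self, static_phantom):
        stack, _ = static_phantom
        aligned, shift = fm.align_channels(stack, manual_shift=(2, 1))
        assert shift == (2, 1)
        np.testing.assert_array_equal(
            aligned.acceptor, np.roll(stack.acceptor, (1, 2), axis=(1, 2)))

    def test_boundary_shift_warns(self):
        cfg = noise_free(n_frames=4, channel_misalignment=(3, 0),
                         striated_patches=self.PATCH)
        stack, _ = fm.simulate_timelapse(cfg)
        with pytest.warns(UserWarning, match="boundary"):
            fm.align_channels(stack, max_shift=3)


class TestBinStack:
    def test_temporal_average_preserves_constant(self, static_phantom):
        stack, _ = static_phantom
        # six-frame temporal binning, the protocol's trace preprocessing
        binned = fm.bin_stack(stack, temporal_factor=6, method="average")
        assert binned.n_frames == stack.n_frames // 6
        np.testing.assert_allclose(binned.donor[0], stack.donor[0])
        assert binned.frame_interval == 6 * stack.frame_interval

    def test_spatial_sum_two_by_two(self):
        frame = np.array([[10.0, 20.0], [30.0, 40.0]])[None]
        stack = fm.TwoChannelStack(frame, frame.copy())
        binned = fm.bin_stack(stack, spatial_factor=2, method="sum")
        assert binned.donor[0, 0, 0] == 100.0

    def test_factor_one_is_identity(self, static_phantom):
        stack, _ = static_phantom
        out = fm.bin_stack(stack, 1, 1)
        np.testing.assert_array_equal(out.donor, stack.donor)

    def test_factor_exceeding_dimension_rejected(self, static_phantom):
        stack, _ = static_phantom
        with pytest.raises(fm.ConfigError):
            fm.bin_stack(stack, temporal_factor=1000)

    def test_trailing_remainder_dropped(self, rng):
        arr = rng.random((7, 6, 6))
        stack = fm.TwoChannelStack(arr, arr.copy())
        binned = fm.bin_stack(stack, temporal_factor=3)
        assert binned.n_frames == 2
        np.testing.assert_allclose(binned.donor[0], arr[:3].mean(axis=0))

    @given(st.integers(1, 4))
    @settings(max_examples=8, derandomize=True)
    def test_sum_scales_constant_by_block_size(self, k):
        arr = np.full((4, 8, 8), 7.0)
        stack = fm.TwoChannelStack(arr, arr.copy())
        out = fm.bin_stack(stack, spatial_factor=k, method="sum")
        np.testing.assert_allclose(out.donor, 7.0 * k * k)


class TestSubtractBackground:
    def test_uniform_frame_zeroed(self):
        arr = np.full((3, 10, 10), 100.0)
        stack = fm.TwoChannelStack(arr, arr.copy())
        out = fm.subtract_background(stack,
                                     fm.RoiPolygon.rectangle(1, 1, 5, 5))
        np.testing.assert_array_equal(out.donor, 0.0)

    def test_wall_minus_background(self):
        arr = np.full((1, 10, 10), 30.0)
        arr[0, 5, 5] = 130.0
        stack = fm.TwoChannelStack(arr, arr.copy())
        out = fm.subtract_background(stack,
                                     fm.RoiPolygon.rectangle(0, 0, 3, 3))
        assert out.donor[0, 5, 5] == 100.0

    def test_commutes_with_uniform_offset(self, rng):
        arr = rng.random((4, 12, 12)) * 50 + 100
        stack = fm.TwoChannelStack(arr, arr.copy())
        bg = fm.RoiPolygon.rectangle(0, 0, 4, 4)
        base = fm.subtract_background(stack, bg)
        shifted = fm.TwoChannelStack(arr + 37.0, arr + 37.0, 5.0)
        off = fm.subtract_background(shifted, bg)
        np.testing.assert_allclose(off.donor, base.donor, atol=1e-9)


class TestNormalizeBaseline:
    def test_constant_series_gives_zero(self):
        out = fm.normalize_baseline(np.full(10, 3.3), range(5))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_doubling_gives_one(self):
        x = np.array([1.0, 1.0, 2.0])
        np.testing.assert_allclose(fm.normalize_baseline(x, [0, 1]),
                                   [0, 0, 1.0])

    def test_ratio_step_gives_half(self):
        x = np.array([0.8] * 5 + [1.2] * 5)
        assert fm.normalize_baseline(x, range(5))[-1] == pytest.approx(0.5)

    def test_zero_baseline_rejected(self):
        with pytest.raises(fm.NormalizationError):
            fm.normalize_baseline(np.zeros(5), range(3))

    def test_empty_or_out_of_range_baseline_rejected(self):
        with pytest.raises(fm.NormalizationError):
            fm.normalize_baseline(np.ones(5), [])
        with pytest.raises(fm.NormalizationError):
            fm.normalize_baseline(np.ones(5), [7])

    @given(st.floats(1e-3, 1e3))
    @settings(max_examples=30, derandomize=True)
    def test_invariant_to_multiplicative_rescaling(self, scale):
        x = np.array([1.0, 1.1, 0.9, 1.5, 2.0])
        a = fm.normalize_baseline(x, range(3))
        b = fm.normalize_baseline(scale * x, range(3))
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-12)
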