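"""Preprocessing pipeline: centering, channel selection, side swap,
interpolation and sliding windows."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from imuhar.asymmetry import segment_asymmetry
from imuhar.layout import RAW_LAYOUT, acc_gyro_subset, subset_channels
from imuhar.preprocessing import (
    ADL_CONFIG,
    ROM_CONFIG,
    PreprocessConfig,
    interpolate_segment,
    preprocess_dataset,
    preprocess_segment,
    select_channels,
    slide_windows,
    swap_sides,
    window_count,
    zero_center,
)

from conftest import make_segment


class TestZeroCenter:
    def test_hand_example(self):
        values = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 45))
        out = zero_center(make_segment(values))
        assert np.allclose(out.values[:, 0], [-1.0, 0.0, 1.0])

    def test_constant_channel_becomes_zero(self):
        out = zero_center(make_segment(np.full((100, 45), 5.0)))
        assert np.allclose(out.values, 0.0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_idempotence(self, seed):
        values = np.random.default_rng(seed).normal(size=(20, 45))
        once = zero_center(make_segment(values))
        twice = zero_center(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)
        assert np.all(np.abs(twice.values.mean(axis=0)) < 1e-9)


class TestSelectChannels:
    def test_default_subset_gives_30_ordered_channels(self):
        seg = make_segment(np.arange(45, dtype=float)[None].repeat(4, axis=0))
        out = select_channels(seg, acc_gyro_subset())
        assert out.values.shape[1] == 30
        assert out.channels[:6] == [(1, "acc", "x"), (1, "acc", "y"), (1, "acc", "z"),
                                    (1, "gyro", "x"), (1, "gyro", "y"), (1, "gyro", "z")]
        assert not any(m == "mag" for _, m, _ in out.channels)

    @pytest.mark.parametrize(
        "subset,n", [(acc_gyro_subset([1]), 6), ([(1, "acc")], 3)]
    )
    def test_single_sensor_ablation_subsets(self, subset, n):
        seg = make_segment(np.zeros((4, 45)))
        assert select_channels(seg, subset).values.shape[1] == n

    def test_unknown_sensor_raises(self):
        with pytest.raises(KeyError):
            select_channels(make_segment(np.zeros((4, 45))), [(9, "acc")])


class TestSwapSides:
    def _sided_segment(self):
        values = np.zeros((10, 45))
        for i, (s, m, a) in enumerate(RAW_LAYOUT.channels()):
            values[:, i] = s  # mark every channel with its sensor id
        return make_segment(values)

    def test_swap_exchanges_sensor_blocks_and_fixes_trunk(self):
        out = swap_sides(self._sided_segment())
        for i, (s, m, a) in enumerate(out.channels):
            expected = {1: 2, 2: 1, 3: 3, 4: 5, 5: 4}[s]
            assert np.all(out.values[:, i] == expected)

    def test_swap_is_an_involution(self, rng):
        seg = make_segment(rng.normal(size=(30, 45)))
        back = swap_sides(swap_sides(seg))
        assert np.array_equal(back.values, seg.values)

    def test_swap_flips_asymmetry_sign(self, small_rom_dataset):
        seg = small_rom_dataset.dataset.segments[0]
        s = segment_asymmetry(seg).s_asym
        s_swapped = segment_asymmetry(swap_sides(seg)).s_asym
        assert s_swapped == pytest.approx(-s, abs=1e-12)

    def test_swap_on_30_channel_layout(self, rng):
        seg = make_segment(rng.normal(size=(10, 45)))
        sub = select_channels(seg, acc_gyro_subset())
        assert np.array_equal(swap_sides(swap_sides(sub)).values, sub.values)


class TestInterpolation:
    def test_resamples_to_target_length(self, rng):
        seg = make_segment(rng.normal(size=(500, 45)))
        assert len(interpolate_segment(seg, 1000)) == 1000

    def test_identity_when_length_already_matches(self, rng):
        values = rng.normal(size=(64, 45))
        out = interpolate_segment(make_segment(values), 64)
        assert np.allclose(out.values, values, atol=1e-12)

    @pytest.mark.parametrize("n_in,n_out", [(7, 100), (333, 50), (2, 1000)])
    def test_linear_ramp_is_reproduced_exactly(self, n_in, n_out):
        ramp = np.linspace(0.0, 1.0, n_in)
        values = np.tile(ramp[:, None], (1, 45))
        out = interpolate_segment(make_segment(values), n_out)
        expected = np.linspace(0.0, 1.0, n_out)
        assert np.allclose(out.values[:, 0], expected, atol=1e-12)
        # endpoints exact
        assert out.values[0, 0] == 0.0 and out.values[-1, 0] == 1.0

    def test_too_short_segment_raises(self):
        with pytest.raises(ValueError):
            interpolate_segment(make_segment(np.zeros((1, 45))), 100)


class TestSlidingWindows:
    @pytest.mark.parametrize(
        "length,window,stride,expected",
        [(1000, 200, 42, 20), (3700, 740, 150, 20), (200, 200, 42, 1)],
    )
    def test_window_count_arithmetic(self, length, window, stride, expected):
        assert window_count(length, window, stride) == expected

    def test_windows_cover_strided_offsets(self, rng):
        cfg = PreprocessConfig(target_length=100, window_size=40, stride=20,
                               windows_per_segment=4)
        values = rng.normal(size=(100, 45))
        seg = select_channels(make_segment(values), acc_gyro_subset())
        windows = slide_windows(seg, cfg)
        assert len(windows) == 4
        for i, w in enumerate(windows):
            assert np.array_equal(w.values, seg.values[i * 20 : i * 20 + 40])
            assert w.window_index == i

    def test_single_window_equals_segment(self, rng):
        cfg = PreprocessConfig(target_length=200, window_size=200, stride=42,
                               windows_per_segment=1)
        seg = make_segment(rng.normal(size=(200, 45)))
        [w] = slide_windows(seg, cfg)
        assert np.array_equal(w.values, seg.values)

    def test_wrong_length_segment_raises(self, rng):
        seg = make_segment(rng.normal(size=(999, 45)))
        with pytest.raises(ValueError, match="interpolate"):
            slide_windows(seg, ROM_CONFIG)

    def test_invalid_config_window_count_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(target_length=1000, window_size=200, stride=50,
                             windows_per_segment=20)


class TestFullPipeline:
    def test_task_presets_produce_20_windows_of_documented_shape(
        self, small_rom_dataset
    ):
        seg = small_rom_dataset.dataset.segments[0]
        windows = slide_windows(preprocess_segment(seg, ROM_CONFIG), ROM_CONFIG)
        assert len(windows) == 20
        assert windows[0].values.shape == (200, 30)
        windows = slide_windows(preprocess_segment(seg, ADL_CONFIG), ADL_CONFIG)
        assert len(windows) == 20
        assert windows[0].values.shape == (740, 30)

    def test_every_segment_contributes_equal_window_count(self, small_rom_dataset):
        cfg = PreprocessConfig(target_length=290, window_size=100, stride=10,
                               windows_per_segment=20)
        windows, processed = preprocess_dataset(small_rom_dataset.dataset, cfg)
        n_segments = len(small_rom_dataset.dataset.segments)
        assert len(windows) == n_segments * 20
        assert len(processed) == n_segments
        per_key: dict = {}
        for w in windows:
            per_key[w.segment_key] = per_key.get(w.segment_key, 0) + 1
        assert set(per_key.values()) == {20}

    def test_disabling_swap_changes_only_left_hemiparesis_output(
        self, small_rom_dataset
    ):
        cfg = PreprocessConfig(target_length=290, window_size=100, stride=10,
                               windows_per_segment=20)
        cfg_noswap = PreprocessConfig(
            target_length=290, window_size=100, stride=10, windows_per_segment=20,
            swap_sides_for_left_hemiparesis=False,
        )
        for seg in small_rom_dataset.dataset.segments:
            with_swap = preprocess_segment(seg, cfg).values
            without = preprocess_segment(seg, cfg_noswap).values
            if seg.hemiparesis_side == "left":
                assert not np.allclose(with_swap, without)
            else:
                assert np.allclose(with_swap, without)
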