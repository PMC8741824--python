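"""Unit and property tests for the four greenness segmenters."""

import colorsys

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from weedscan import (
    ThresholdProfile,
    exg,
    exhsv_mask,
    get_profile,
    hsv_mask,
    load_profile,
    nexg,
    rgb_to_hsv8,
    save_profile,
)


def frame_of(*pixels):
    """1×N RGB frame from pixel tuples."""
    return np.array([list(pixels)], dtype=np.uint8)


class TestExG:
    @pytest.mark.parametrize(
        "pixel,expected",
        [
            ((100, 100, 100), 0),  # gray: 2G-R-B = 0
            ((50, 150, 40), 210),  # 2*150-50-40
            ((0, 0, 255), 0),  # raw -255 clips to 0
            ((0, 255, 0), 255),  # raw 510 clips to 255
        ],
    )
    def test_pixel_values(self, pixel, expected):
        assert exg(frame_of(pixel))[0, 0] == expected

    def test_rejects_non_rgb_input(self):
        with pytest.raises(ValueError):
            exg(np.zeros((4, 4), dtype=np.uint8))

    @given(st.integers(0, 255), st.integers(0, 255), st.integers(0, 255),
           st.integers(-50, 50))
    @settings(deadline=None, derandomize=True)
    def test_brightness_offset_invariance_without_clipping(self, r, g, b, c):
        """Adding a constant to all channels cancels in 2G-R-B when neither
        the channels nor the raw index clip."""
        raw = 2 * g - r - b
        shifted = (r + c, g + c, b + c)
        if not all(0 <= v <= 255 for v in shifted) or not 0 <= raw <= 255:
            return
        assert exg(frame_of(shifted))[0, 0] == exg(frame_of((r, g, b)))[0, 0]


class TestNExG:
    @pytest.mark.parametrize(
        "pixel,expected",
        [
            ((100, 100, 100), 0),  # r = g = b
            ((0, 255, 0), 255),  # g = 1 -> 510, clipped
            ((0, 0, 0), 0),  # zero-sum guard
        ],
    )
    def test_pixel_values(self, pixel, expected):
        assert nexg(frame_of(pixel))[0, 0] == expected

    @given(st.integers(1, 255))
    @settings(deadline=None, derandomize=True)
    def test_gray_frames_map_to_zero(self, level):
        frame = np.full((8, 8, 3), level, dtype=np.uint8)
        assert not exg(frame).any()
        assert not nexg(frame).any()


def per_pixel_oracle(frame):
    """Loop-per-pixel scalar evaluation of the ExG/NExG/HSV formulas."""
    h, w = frame.shape[:2]
    exg_o = np.zeros((h, w), dtype=np.uint8)
    nexg_o = np.zeros((h, w), dtype=np.uint8)
    hsv_o = np.zeros((h, w, 3), dtype=np.uint8)
    for i in range(h):
        for j in range(w):
            r, g, b = (int(v) for v in frame[i, j])
            exg_o[i, j] = min(max(2 * g - r - b, 0), 255)
            total = r + g + b
            if total > 0:
                idx = 255.0 * (2 * g - r - b) / total
                nexg_o[i, j] = int(min(max(round(idx), 0), 255))
            hh, ss, vv = colorsys.rgb_to_hsv(r / 255.0, g / 255.0, b / 255.0)
            hsv_o[i, j] = (round(hh * 180.0) % 180, round(ss * 255.0),
                           round(vv * 255.0))
    return exg_o, nexg_o, hsv_o


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_vectorised_maps_equal_per_pixel_oracle(seed):
    frame = np.random.default_rng(seed).integers(0, 256, (5, 5, 3), dtype=np.uint8)
    exg_o, nexg_o, hsv_o = per_pixel_oracle(frame)
    np.testing.assert_array_equal(exg(frame), exg_o)
    np.testing.assert_array_equal(nexg(frame), nexg_o)
    np.testing.assert_array_equal(rgb_to_hsv8(frame), hsv_o)


class TestHSVMask:
    def test_saturated_bright_green_excluded_by_day_bands(self):
        # pure green has H=60 inside the band but S=255 and V=255 above the
        # saturation/value caps that reject glare
        mask = hsv_mask(frame_of((0, 255, 0)), get_profile("day", "hsv"))
        assert mask[0, 0] == 0

    def test_black_pixel_below_value_floor(self):
        assert hsv_mask(frame_of((0, 0, 0)), get_profile("day", "hsv"))[0, 0] == 0

    def test_mid_green_inside_all_bands(self):
        profile = ThresholdProfile(hue_min=30, hue_max=92, sat_min=10,
                                   sat_max=250, val_min=15, val_max=250)
        assert hsv_mask(frame_of((40, 160, 40)), profile)[0, 0] == 255

    @pytest.mark.parametrize("preset,algorithm", [("day", "hsv"), ("night", "hsv"),
                                                  ("day", "exhsv"), ("night", "exhsv")])
    def test_masks_are_two_valued(self, preset, algorithm, rng):
        frame = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        profile = get_profile(preset, algorithm)
        fn = hsv_mask if algorithm == "hsv" else exhsv_mask
        assert set(np.unique(fn(frame, profile))) <= {0, 255}


class TestExHSVMask:
    def test_fails_when_greenness_index_below_band(self):
        profile = get_profile("day", "exhsv")
        # faintly green gray: H=60, S~10, V=104 all inside the bands, but
        # NExG = 255*8/304 ~ 7 sits below the 13 floor
        pixel = (100, 104, 100)
        assert hsv_mask(frame_of(pixel), profile)[0, 0] == 255
        assert exhsv_mask(frame_of(pixel), profile)[0, 0] == 0

    def test_passes_when_both_conditions_hold(self):
        profile = get_profile("day", "exhsv")
        pixel = (60, 120, 60)  # NExG = 255*120/240 = 128, inside 13-200
        index = int(nexg(frame_of(pixel))[0, 0])
        assert profile.exg_min <= index <= profile.exg_max
        assert exhsv_mask(frame_of(pixel), profile)[0, 0] == 255

    def test_all_gray_frame_yields_empty_mask(self, gray_frame):
        assert not exhsv_mask(gray_frame, get_profile("day", "exhsv")).any()

    def test_subset_of_hsv_mask(self, rng):
        frame = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        profile = get_profile("day", "exhsv")
        assert (exhsv_mask(frame, profile) <= hsv_mask(frame, profile)).all()

    def test_raw_exg_variant_switch(self, rng):
        frame = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        raw = get_profile("day", "exhsv", exhsv_green_index="exg")
        index = exg(frame)
        expected = ((index >= raw.exg_min) & (index <= raw.exg_max)
                    & (hsv_mask(frame, raw) > 0))
        np.testing.assert_array_equal(exhsv_mask(frame, raw) > 0, expected)


class TestThresholdProfile:
    def test_band_inversion_rejected(self):
        with pytest.raises(ValueError):
            ThresholdProfile(exg_min=200, exg_max=13)

    def test_even_adaptive_block_rejected(self):
        with pytest.raises(ValueError):
            ThresholdProfile(adaptive_block_size=30)

    def test_unknown_preset_and_algorithm(self):
        with pytest.raises(ValueError):
            get_profile("dusk", "exg")
        with pytest.raises(ValueError):
            get_profile("day", "otsu")

    def test_yaml_round_trip(self, tmp_path):
        profile = get_profile("night", "exhsv")
        path = tmp_path / "profile.yaml"
        save_profile(profile, path)
        assert load_profile(path) == profile

    def test_day_night_presets_differ_in_greenness_floor(self):
        assert get_profile("day", "exg").exg_min == 13
        assert get_profile("night", "exg").exg_min == 29
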