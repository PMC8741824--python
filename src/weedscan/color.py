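"""Colour-based greenness algorithms for fallow weed detection.

Four per-pixel segmenters operate on 8-bit RGB frames:

* ``exg`` — excess green, 2G − R − B, clipped to [0, 255].
* ``nexg`` — excess green on chromatic coordinates r, g, b = R, G, B / (R+G+B),
  rescaled by 255, which suppresses overall-illumination changes.
* ``hsv_mask`` — band thresholds on hue, saturation and value; already binary.
* ``exhsv_mask`` — conjunction of the normalised-greenness band and the HSV
  band mask, trading sensitivity for precision.

Hue uses the half-circle 8-bit convention (0–179, i.e. degrees / 2) so that
green (120°) sits at 60; the shipped day/night band presets assume it.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import yaml
from skimage.color import rgb2hsv

__all__ = [
    "ThresholdProfile",
    "get_profile",
    "load_profile",
    "save_profile",
    "PRESETS",
    "ALGORITHMS",
    "exg",
    "nexg",
    "rgb_to_hsv8",
    "hsv_mask",
    "exhsv_mask",
]

ALGORITHMS = ("exg", "nexg", "hsv", "exhsv")


@dataclass(frozen=True)
class ThresholdProfile:
    """All tunable detection parameters for one algorithm/lighting condition.

    Intensity bounds are inclusive on both ends and expressed on 8-bit
    scales: greenness index and saturation/value on 0–255, hue on 0–179.
    """

    exg_min: int = 13
    exg_max: int = 200
    hue_min: int = 30
    hue_max: int = 92
    sat_min: int = 4
    sat_max: int = 250
    val_min: int = 15
    val_max: int = 250
    min_object_area: int = 10
    adaptive_block_size: int = 31
    adaptive_offset: int = 2
    morph_kernel: int = 3
    profile_name: str = "custom"
    # greenness term used by the combined algorithm: "nexg" (default, the
    # normalised index) or "exg" (raw index)
    exhsv_green_index: str = "nexg"

    def __post_init__(self) -> None:
        for lo, hi in (
            (self.exg_min, self.exg_max),
            (self.hue_min, self.hue_max),
            (self.sat_min, self.sat_max),
            (self.val_min, self.val_max),
        ):
            if lo > hi:
                raise ValueError(f"threshold band min {lo} exceeds max {hi}")
        if self.min_object_area < 0:
            raise ValueError("min_object_area must be >= 0")
        if self.adaptive_block_size < 3 or self.adaptive_block_size % 2 == 0:
            raise ValueError("adaptive_block_size must be odd and >= 3")
        if self.exhsv_green_index not in ("nexg", "exg"):
            raise ValueError("exhsv_green_index must be 'nexg' or 'exg'")


# Shipped day/night presets: manually tuned band thresholds per algorithm.
# Index algorithms share the greenness band; HSV/ExHSV differ in their
# hue/saturation/value bands and the combined algorithm keeps a wider,
# more permissive HSV region because the greenness band does the filtering.
PRESETS: dict[tuple[str, str], ThresholdProfile] = {
    ("day", "exg"): ThresholdProfile(exg_min=13, exg_max=200, profile_name="day-exg"),
    ("day", "nexg"): ThresholdProfile(exg_min=13, exg_max=200, profile_name="day-nexg"),
    ("day", "exhsv"): ThresholdProfile(
        exg_min=13, exg_max=200, hue_min=30, hue_max=92,
        sat_min=4, sat_max=250, val_min=15, val_max=250,
        profile_name="day-exhsv",
    ),
    ("day", "hsv"): ThresholdProfile(
        hue_min=35, hue_max=84, sat_min=10, sat_max=220,
        val_min=50, val_max=200, profile_name="day-hsv",
    ),
    ("night", "exg"): ThresholdProfile(exg_min=29, exg_max=200, profile_name="night-exg"),
    ("night", "nexg"): ThresholdProfile(exg_min=29, exg_max=200, profile_name="night-nexg"),
    ("night", "exhsv"): ThresholdProfile(
        exg_min=29, exg_max=200, hue_min=30, hue_max=92,
        sat_min=10, sat_max=250, val_min=60, val_max=250,
        profile_name="night-exhsv",
    ),
    ("night", "hsv"): ThresholdProfile(
        hue_min=45, hue_max=80, sat_min=75, sat_max=200,
        val_min=46, val_max=240, profile_name="night-hsv",
    ),
}


def get_profile(preset: str, algorithm: str, **overrides) -> ThresholdProfile:
    """Return a shipped preset ("day" or "night") for one of the four
    algorithms, optionally overriding individual fields."""
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    try:
        profile = PRESETS[(preset, algorithm)]
    except KeyError:
        raise ValueError(f"unknown preset {preset!r}; expected 'day' or 'night'") from None
    return replace(profile, **overrides) if overrides else profile


def load_profile(path: str | Path) -> ThresholdProfile:
    """Load a profile from a YAML (or JSON) mapping with field-named keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"profile file {path} does not contain a mapping")
    return ThresholdProfile(**data)


def save_profile(profile: ThresholdProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(profile), fh, sort_keys=False)


def _validate_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB frame, got shape {frame.shape}")
    return frame


def exg(frame: np.ndarray) -> np.ndarray:
    """Excess-green index map: clip(2G − R − B, 0, 255) as uint8.

    Computed in a signed intermediate so 8-bit arithmetic cannot wrap.
    """
    frame = _validate_frame(frame)
    r, g, b = (frame[..., i].astype(np.int32) for i in range(3))
    return np.clip(2 * g - r - b, 0, 255).astype(np.uint8)


def nexg(frame: np.ndarray) -> np.ndarray:
    """Normalised excess-green index map, rescaled to 8-bit.

    Chromatic coordinates r, g, b are each channel divided by R+G+B; the
    index 2g − r − b (range −1..2 in theory) is scaled by 255 and clipped to
    [0, 255]. Black pixels (R+G+B = 0) map to 0: black is never vegetation.
    """
    frame = _validate_frame(frame)
    chans = frame.astype(np.float64)
    total = chans.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        index = 255.0 * (2 * chans[..., 1] - chans[..., 0] - chans[..., 2]) / total
    index[total == 0] = 0.0
    return np.clip(np.rint(index), 0, 255).astype(np.uint8)


def rgb_to_hsv8(frame: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB frame to 8-bit HSV with hue on 0–179.

    Hue is degrees / 2 (the half-circle convention, so the full circle fits
    in one byte); saturation and value are scaled to 0–255.
    """
    frame = _validate_frame(frame)
    hsv = rgb2hsv(frame.astype(np.float64) / 255.0)
    h8 = np.rint(hsv[..., 0] * 180.0) % 180
    s8 = np.rint(hsv[..., 1] * 255.0)
    v8 = np.rint(hsv[..., 2] * 255.0)
    return np.stack([h8, s8, v8], axis=-1).astype(np.uint8)


def hsv_mask(frame: np.ndarray, profile: ThresholdProfile) -> np.ndarray:
    """Binary vegetation mask from inclusive hue/saturation/value bands.

    A pixel is 255 iff all three channels lie within the profile's bands;
    the result is already binary and needs no adaptive-threshold stage.
    """
    hsv = rgb_to_hsv8(frame)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    inside = (
        (h >= profile.hue_min) & (h <= profile.hue_max)
        & (s >= profile.sat_min) & (s <= profile.sat_max)
        & (v >= profile.val_min) & (v <= profile.val_max)
    )
    return np.where(inside, 255, 0).astype(np.uint8)


def exhsv_mask(frame: np.ndarray, profile: ThresholdProfile) -> np.ndarray:
    """Combined greenness-index + HSV mask (pixelwise intersection).

    A pixel passes iff its greenness index (normalised by default, raw ExG
    when ``profile.exhsv_green_index == "exg"``) lies within
    [exg_min, exg_max] *and* it falls inside the HSV bands. Downstream this
    mask is refined by the adaptive-threshold stage like the index
    algorithms' grayscale regions.
    """
    index = exg(frame) if profile.exhsv_green_index == "exg" else nexg(frame)
    in_band = (index >= profile.exg_min) & (index <= profile.exg_max)
    return np.where(in_band & (hsv_mask(frame, profile) > 0), 255, 0).astype(np.uint8)
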