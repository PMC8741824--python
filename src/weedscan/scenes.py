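"""Parametric synthetic field scenes with exact ground truth.

Renders the situations a fallow weed detector meets in practice: green
broadleaf weeds of varying hue, size and blur on red-orange or dark-brown
soil, pale straw stubble streaks, and near-white specular glare patches
that fool raw greenness indices under bright sun. Every painted weed is
recorded in a ground-truth set (centroid + pre-blur pixel area), so
precision and recall of any pipeline configuration can be measured exactly.

Scene batteries bundle named parameter regimes:

* ``day_green`` — high-contrast green discs on clean soil; a colour-based
  detector should recover every weed with no false positives.
* ``night`` — the same kind of weeds under dim artificial illumination.
* ``stubble_glare`` — straw streaks and specular highlights; raw excess
  green fires on the glare, the combined index + HSV algorithm largely
  does not.
* ``grass_thin`` — thin grass blades that blur into the background.
* ``purple_stressed`` — grey/purple-green rosettes whose hue falls outside
  the green bands, the canonical missed-detection case.

All randomness flows through one seeded generator per scene; identical
specs render identical frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.color import hsv2rgb
from skimage.draw import disk as draw_disk, ellipse as draw_ellipse, polygon as draw_polygon
from skimage.filters import gaussian

from .evaluate import GroundTruth, GroundTruthSet

__all__ = [
    "WeedSpec",
    "SceneSpec",
    "SyntheticScene",
    "render_scene",
    "scene_battery",
    "BATTERY_STYLES",
    "save_scene",
]

BATTERY_STYLES = ("day_green", "night", "stubble_glare", "grass_thin", "purple_stressed")

#: base soil colours (R, G, B); green channel kept below red so bare soil
#: has zero excess green
_BACKGROUNDS = {
    "red_orange_soil": (152, 92, 62),
    "dark_brown_soil": (82, 62, 46),
    "tilled": (76, 58, 44),
}

_STRAW_RGB = (212, 192, 128)  # pale stubble: weak positive excess green
_SPECULAR_RGB = (242, 255, 240)  # glare: near-white, value ~255, hue off-green


@dataclass(frozen=True)
class WeedSpec:
    """One synthetic weed: where it sits and how it looks.

    ``hue_deg`` is on the full 0–360° circle; saturation/value are 8-bit.
    ``radius`` is the overall plant radius in pixels; ``leaf_count`` only
    matters for rosette and grass shapes.
    """

    centroid: tuple[float, float]  # (cx, cy) pixels
    radius: int
    hue_deg: float
    saturation: int
    value: int
    shape: str = "disc"  # disc | rosette | grass_blade
    leaf_count: int = 5


@dataclass(frozen=True)
class SceneSpec:
    dims: tuple[int, int] = (416, 320)  # (width, height)
    background: str = "red_orange_soil"
    stubble_density: float = 0.0
    specular_fraction: float = 0.0
    weeds: tuple[WeedSpec, ...] = ()
    blur_sigma: float = 0.6
    illumination_gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background not in _BACKGROUNDS:
            raise ValueError(f"unknown background {self.background!r}")
        for frac in (self.stubble_density, self.specular_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("density fractions must lie in [0, 1]")
        w, h = self.dims
        for weed in self.weeds:
            cx, cy = weed.centroid
            if not (0 <= cx < w and 0 <= cy < h):
                raise ValueError(f"weed centroid {weed.centroid} outside {self.dims}")
            if weed.radius < 1:
                raise ValueError("weed radius must be >= 1 pixel")
            if weed.shape not in ("disc", "rosette", "grass_blade"):
                raise ValueError(f"unknown weed shape {weed.shape!r}")


@dataclass(frozen=True)
class SyntheticScene:
    frame: np.ndarray  # H x W x 3 uint8
    truth: GroundTruthSet
    spec: SceneSpec


def _weed_rgb(weed: WeedSpec) -> np.ndarray:
    hsv = np.array([[(weed.hue_deg % 360) / 360.0, weed.saturation / 255.0,
                     weed.value / 255.0]])
    return hsv2rgb(hsv.reshape(1, 1, 3)).reshape(3) * 255.0


def _thick_line(rng: np.random.Generator, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Random rotated-rectangle footprint for a stubble straw."""
    h, w = shape
    cy, cx = rng.uniform(0, h), rng.uniform(0, w)
    angle = rng.uniform(0, np.pi)
    length = rng.uniform(25, 70)
    width = rng.uniform(1.5, 3.5)
    dy, dx = np.sin(angle), np.cos(angle)
    ny, nx = -dx, dy  # unit normal
    half_l, half_w = length / 2, width / 2
    ys = [cy - dy * half_l - ny * half_w, cy - dy * half_l + ny * half_w,
          cy + dy * half_l + ny * half_w, cy + dy * half_l - ny * half_w]
    xs = [cx - dx * half_l - nx * half_w, cx - dx * half_l + nx * half_w,
          cx + dx * half_l + nx * half_w, cx + dx * half_l - nx * half_w]
    return draw_polygon(ys, xs, shape=shape)


def _paint_weed(canvas: np.ndarray, weed: WeedSpec, rng: np.random.Generator) -> int:
    """Draw one weed onto the float canvas; returns painted pixel count."""
    h, w = canvas.shape[:2]
    cx, cy = weed.centroid
    colour = _weed_rgb(weed)
    painted = np.zeros((h, w), dtype=bool)
    if weed.shape == "disc":
        rr, cc = draw_disk((cy, cx), weed.radius, shape=(h, w))
        painted[rr, cc] = True
    elif weed.shape == "rosette":
        angles = np.linspace(0, 2 * np.pi, weed.leaf_count, endpoint=False)
        angles = angles + rng.uniform(0, 2 * np.pi / weed.leaf_count)
        for ang in angles:
            lcy = cy + np.sin(ang) * weed.radius / 2
            lcx = cx + np.cos(ang) * weed.radius / 2
            rr, cc = draw_ellipse(
                lcy, lcx, weed.radius / 1.8, max(weed.radius / 4.0, 1.0),
                shape=(h, w), rotation=-(ang + np.pi / 2),
            )
            painted[rr, cc] = True
    else:  # grass_blade: a few thin blades fanning out of the centre
        for _ in range(max(weed.leaf_count, 2)):
            ang = rng.uniform(0, 2 * np.pi)
            length = weed.radius * rng.uniform(1.5, 2.5)
            tip_y, tip_x = cy + np.sin(ang) * length, cx + np.cos(ang) * length
            ny, nx = -np.cos(ang), np.sin(ang)
            ys = [cy - ny, cy + ny, tip_y + ny, tip_y - ny]
            xs = [cx - nx, cx + nx, tip_x + nx, tip_x - nx]
            rr, cc = draw_polygon(ys, xs, shape=(h, w))
            painted[rr, cc] = True
    jitter = rng.normal(0, 4, size=3)
    canvas[painted] = np.clip(colour + jitter, 0, 255)
    return int(painted.sum())


def render_scene(spec: SceneSpec) -> SyntheticScene:
    """Render a scene spec to an 8-bit RGB frame plus exact ground truth.

    Layer order: soil texture, stubble straws, specular glare, weeds; then
    Gaussian blur and an illumination gain over the whole frame. The truth
    records each weed's centroid and painted (pre-blur) pixel area.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.dims
    base = np.array(_BACKGROUNDS[spec.background], dtype=np.float64)
    canvas = np.clip(
        base + rng.normal(0, 4, size=(h, w, 3)), 0, 255
    )
    if spec.background == "tilled":
        # shallow tillage rows: a gentle horizontal brightness ripple
        rows = 12 * np.sin(np.arange(h)[:, None] / 9.0)
        canvas = np.clip(canvas + rows[..., None], 0, 255)

    n_straw = int(round(spec.stubble_density * 120))
    for _ in range(n_straw):
        rr, cc = _thick_line(rng, (h, w))
        shade = rng.uniform(0.85, 1.05)
        canvas[rr, cc] = np.clip(np.array(_STRAW_RGB) * shade, 0, 255)

    n_glare = int(round(spec.specular_fraction * 24))
    for _ in range(n_glare):
        gy, gx = rng.uniform(0, h), rng.uniform(0, w)
        ry, rx = rng.uniform(2.5, 6.0), rng.uniform(2.5, 6.0)
        rr, cc = draw_ellipse(gy, gx, ry, rx, shape=(h, w))
        canvas[rr, cc] = _SPECULAR_RGB

    annotations = []
    for i, weed in enumerate(spec.weeds):
        area = _paint_weed(canvas, weed, rng)
        annotations.append(GroundTruth(id=i, centroid=weed.centroid))

    if spec.blur_sigma > 0:
        canvas = gaussian(canvas, sigma=spec.blur_sigma, channel_axis=-1,
                          preserve_range=True)
    canvas = np.clip(canvas * spec.illumination_gain, 0, 255)
    frame = np.rint(canvas).astype(np.uint8)
    return SyntheticScene(frame=frame, truth=GroundTruthSet(tuple(annotations)), spec=spec)


def _sample_positions(
    rng: np.random.Generator, n: int, dims: tuple[int, int],
    radii: list[int], margin: int = 16, gap: int = 10,
) -> list[tuple[float, float]]:
    """Rejection-sample weed centres that neither touch the border nor
    each other (so each weed stays a separate connected component)."""
    w, h = dims
    centres: list[tuple[float, float]] = []
    attempts = 0
    while len(centres) < n and attempts < 20_000:
        attempts += 1
        i = len(centres)
        cx = rng.uniform(margin + radii[i], w - margin - radii[i])
        cy = rng.uniform(margin + radii[i], h - margin - radii[i])
        ok = all(
            np.hypot(cx - ox, cy - oy) >= radii[i] + radii[j] + gap
            for j, (ox, oy) in enumerate(centres)
        )
        if ok:
            centres.append((round(cx, 1), round(cy, 1)))
    if len(centres) < n:
        raise RuntimeError("could not place weeds without overlap")
    return centres


def _style_spec(style: str, rng: np.random.Generator, seed: int) -> SceneSpec:
    dims = (416, 320)
    if style == "day_green":
        n = int(rng.integers(3, 7))
        radii = [int(rng.integers(6, 11)) for _ in range(n)]
        centres = _sample_positions(rng, n, dims, radii)
        weeds = tuple(
            WeedSpec(
                centroid=c, radius=r, shape="disc",
                hue_deg=float(rng.uniform(95, 145)),
                saturation=int(rng.integers(110, 151)),
                value=int(rng.integers(110, 151)),
            )
            for c, r in zip(centres, radii)
        )
        return SceneSpec(dims=dims, background="red_orange_soil", weeds=weeds,
                         blur_sigma=0.6, seed=seed)
    if style == "night":
        n = int(rng.integers(2, 6))
        radii = [int(rng.integers(6, 11)) for _ in range(n)]
        centres = _sample_positions(rng, n, dims, radii)
        weeds = tuple(
            WeedSpec(
                centroid=c, radius=r, shape="disc",
                hue_deg=float(rng.uniform(100, 140)),
                saturation=int(rng.integers(120, 151)),
                value=int(rng.integers(120, 151)),
            )
            for c, r in zip(centres, radii)
        )
        return SceneSpec(dims=dims, background="dark_brown_soil", weeds=weeds,
                         blur_sigma=0.8, illumination_gain=0.6, seed=seed)
    if style == "stubble_glare":
        n = int(rng.integers(2, 5))
        radii = [int(rng.integers(6, 10)) for _ in range(n)]
        centres = _sample_positions(rng, n, dims, radii)
        weeds = tuple(
            WeedSpec(
                centroid=c, radius=r, shape="disc",
                hue_deg=float(rng.uniform(100, 140)),
                saturation=int(rng.integers(110, 151)),
                value=int(rng.integers(110, 151)),
            )
            for c, r in zip(centres, radii)
        )
        return SceneSpec(dims=dims, background="red_orange_soil",
                         stubble_density=0.8, specular_fraction=0.5,
                         weeds=weeds, blur_sigma=0.5, seed=seed)
    if style == "grass_thin":
        n = int(rng.integers(3, 7))
        radii = [int(rng.integers(8, 13)) for _ in range(n)]
        centres = _sample_positions(rng, n, dims, radii, gap=24)
        weeds = tuple(
            WeedSpec(
                centroid=c, radius=r, shape="grass_blade", leaf_count=3,
                hue_deg=float(rng.uniform(95, 135)),
                saturation=int(rng.integers(90, 131)),
                value=int(rng.integers(100, 141)),
            )
            for c, r in zip(centres, radii)
        )
        return SceneSpec(dims=dims, background="dark_brown_soil", weeds=weeds,
                         blur_sigma=1.2, seed=seed)
    if style == "purple_stressed":
        n = int(rng.integers(3, 7))
        radii = [int(rng.integers(6, 11)) for _ in range(n)]
        centres = _sample_positions(rng, n, dims, radii)
        weeds = tuple(
            WeedSpec(
                centroid=c, radius=r, shape="rosette", leaf_count=5,
                hue_deg=float(rng.uniform(270, 320)),
                saturation=int(rng.integers(60, 111)),
                value=int(rng.integers(90, 141)),
            )
            for c, r in zip(centres, radii)
        )
        return SceneSpec(dims=dims, background="red_orange_soil", weeds=weeds,
                         blur_sigma=0.8, seed=seed)
    raise ValueError(f"unknown battery style {style!r}; expected one of {BATTERY_STYLES}")


def scene_battery(style: str, n: int, seed: int = 0) -> list[SyntheticScene]:
    """Render ``n`` scenes drawn from a named parameter regime.

    Reproducible: the same (style, n, seed) always yields the same scenes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if style not in BATTERY_STYLES:
        raise ValueError(f"unknown battery style {style!r}; expected one of {BATTERY_STYLES}")
    master = np.random.default_rng(seed)
    scenes = []
    for _ in range(n):
        scene_seed = int(master.integers(0, 2**31 - 1))
        spec = _style_spec(style, np.random.default_rng(scene_seed), scene_seed)
        scenes.append(render_scene(spec))
    return scenes


def save_scene(scene: SyntheticScene, stem: str | Path) -> tuple[Path, Path]:
    """Write a scene as PNG plus a JSON ground-truth sidecar."""
    import imageio.v3 as iio

    stem = Path(stem)
    png = stem.with_suffix(".png")
    sidecar = stem.with_suffix(".json")
    iio.imwrite(png, scene.frame)
    payload = {
        "spec": {**asdict(scene.spec), "weeds": [asdict(w) for w in scene.spec.weeds]},
        "annotations": [
            {"id": a.id, "cx": a.centroid[0], "cy": a.centroid[1]}
            for a in scene.truth.annotations
        ],
    }
    sidecar.write_text(json.dumps(payload, indent=2))
    return png, sidecar
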