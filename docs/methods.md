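# Methods

## Problem and model

In a fallow field every living plant is a weed, so site-specific weed
control only needs to answer "is there green vegetation here, and in which
lateral strip?". `weedscan` models a camera looking straight down with a
1 m on-ground field of view, frames processed at 416 × 320 px, and four
25 cm actuation zones each tied to a relay channel that opens a nozzle for
a fixed duration when a weed is detected in its strip.

Detection is purely colour-based. Per frame:

1. **Resize** to 416 × 320 (bilinear). The default matches the resolution
   the thresholds were tuned at; all stages accept other sizes.
2. **Greenness.** `ExG = 2G − R − B` computed in signed integers and
   clipped to `[0, 255]`; `NExG` is the same index on chromatic coordinates
   (channel / channel-sum, black pixels defined as 0) scaled by 255; `HSV`
   applies inclusive bands per channel with hue on the 0–179 half-circle
   scale; `ExHSV` requires a pixel to pass both the NExG band and the HSV
   bands (a config switch substitutes raw ExG as the greenness term).
3. **Defined threshold.** Inclusive band on the index: 13–200 by day,
   29–200 by night. The upper bound deliberately rejects extreme index
   values, which in practice come from blown-out or artificial colour
   rather than foliage.
4. **Adaptive threshold.** A pixel survives only if its index exceeds the
   Gaussian-weighted local mean (block 31, offset 2) — so weak uniform
   casts over large areas are rejected and only locally green structure
   remains — intersected with the defined mask. Skipped for HSV, whose
   mask is already binary. We define foreground as `value > local mean +
   offset`; a perfectly flat map therefore yields an empty mask, which is
   the behaviour wanted in weed-free frames.
5. **Morphology.** Opening then closing with a 3 px elliptical footprint,
   one iteration each: removes speckle, bridges pin-holes.
6. **Objects.** 8-connected components; components below 10 px are noise
   and discarded; each survivor becomes an axis-aligned bounding box whose
   centre is the weed centre. Output is sorted by bounding-box origin so
   runs are byte-reproducible.

Zone allocation is `floor(cx · n_zones / frame_width)` on half-open bins,
so every pixel column belongs to exactly one zone. Activations are
deduplicated per zone per frame; a retrigger extends the open interval
(end = now + duration) instead of queueing, keeping a nozzle open over
contiguous weeds. The default duration is 200 ms and is configurable; no
forward-speed/nozzle-lag compensation is modelled.

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| index band (day) | 13–200 | 8-bit intensity | floor rejects soil, cap rejects blown-out colour |
| index band (night) | 29–200 | 8-bit intensity | artificial light raises the soil floor |
| HSV bands (day) | H 35–84, S 10–220, V 50–200 | 8-bit (H half-circle) | brackets foliage green; V cap rejects glare |
| ExHSV bands (day) | H 30–92, S 4–250, V 15–250 | 8-bit | wider than HSV because the index band filters too |
| adaptive block / offset | 31 / 2 | px / intensity | block ≈ largest expected weed at 416 px width |
| morphology kernel | 3 | px | minimal speckle removal |
| min object area | 10 | px | below this, noise dominates |
| zones / FOV | 4 / 1.0 | – / m | 25 cm strips per relay channel |
| activation duration | 200 | ms | order of one frame-to-nozzle pass |
| matching tolerance | 50 | px | ~12% of frame width; scoring is centroid-distance greedy |

The adaptive-threshold weighting (Gaussian), block size and offset, the
morphology shape/iterations, and the matching tolerance are this package's
own choices — the procedure they implement ("defined plus adaptive
threshold, morphological noise removal, minimum object size") leaves them
open, and all are user-overridable.

## Evaluation

Detections are matched to ground-truth weed centres greedily by nearest
centroid within the tolerance, one match per weed, inputs sorted first so
the result is order-invariant; extra detections on an already-matched weed
count as false positives. Precision is undefined (reported `n/a`, never
silently 0) when there are no detections, recall when no weeds are
present. Weed density is count / (transect length × FOV width).

The package ships, as reference data, the per-transect precision/recall
table and site summaries of a seven-transect fallow field trial (five
daylight and two artificially lit night transects, four algorithms, one
missing cell where an algorithm lost detection entirely). `aggregate`
computes means over all present cells, per-algorithm medians across
transects, per-site means across algorithms, and standard errors
(sd/√n, ddof = 1). Missing cells are excluded everywhere. One caveat found
while validating: the trial's published overall standard errors appear
swapped between precision and recall relative to its own table; this
package reports the values computed from the cells.

## Synthetic scenes

The generator emulates the conditions that drive colour-based performance:
soil base colours (red-orange, dark brown, tilled rows) with per-pixel
noise, pale straw streaks, near-white specular glare ellipses, and weeds as
discs, rosettes or thin grass blades with specified HSV colour, followed by
Gaussian blur and an illumination gain. Ground-truth area is the painted
pixel count before blur (blur makes post-hoc area ambiguous). All
randomness flows through one seeded generator per scene.

Battery styles encode study conditions: `day_green` (solid green discs,
radius 6–10 px, hue 95–145°, little blur, clean soil — a detector should
be perfect here), `night` (dim gain, night thresholds apply),
`stubble_glare` (dense straw plus glare; the glare's value ≈ 255 and tiny
normalised-green index make it invisible to ExHSV while raw ExG fires),
`grass_thin` (3 px blades, blur σ = 1.2 — recall drops), and
`purple_stressed` (hue 270–320°, outside every green band — the canonical
miss). Weed colours in green batteries are sampled with `2·V·S/255 ≤ ~180`
so the index stays inside the defined band even at the hue where it peaks.

What passing these batteries does **not** show: real fields add motion
blur from rolling shutters, mixed-pixel edges at much lower
ground-sampling distance, shadows, overlapping canopies and continuous
weed-size distributions. Synthetic recovery at 100% is a correctness check
of the pipeline, not a field-performance claim; the bundled trial table is
the empirical reference for field-scale behaviour.

## Numerical and design notes

- All index maps are clipped to `[0, 255]` and stored as uint8; HSV band
  comparisons are inclusive on both ends.
- Hue sits on the 0–179 half-circle scale even though the other channels
  are 0–255: the shipped green bands (e.g. 30–92) bracket green (60 ≙
  120°) only under that convention.
- Frame I/O converts to R, G, B channel order at the boundary; everything
  internal assumes it.
- Detection lists, CSV logs and rendered scenes are deterministic for
  fixed inputs, configs and seeds.
- Video files are read through imageio when a decoder is available;
  annotated output is written as PNG frame sequences, which need no codec.
- The framerate benchmark reports wall-clock FPS per algorithm on an
  identical frame stream; absolute values and ordering are
  hardware-dependent and are logged, never asserted.

## Known limitations

Colour-only detection misses grey/purple-stressed and thin-leaved weeds by
construction; heavy stubble occludes plants; no specular-reflection
management is implemented beyond the ExHSV value cap; zone timing has no
forward-speed compensation; the hardware relay backend is a plug-in
contract only — the shipped backend is a mock that logs transitions.
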