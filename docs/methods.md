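# Methods

This note documents the models implemented in `apc`, the numerical choices
made, and what the synthetic generators do and do not emulate.

## 1. Physical picture

In phase contrast, light from a ring-shaped condenser aperture (the annulus)
must land on the objective's phase ring in the back focal plane. The liquid
meniscus in a multiwell plate refracts the illumination cone, so the annulus
image in the pupil is displaced radially outward as the field of view moves
from the well center toward the rim, and slightly distorted (the image of a
circle becomes mildly elliptical). The displacement grows monotonically with
radial position in the well. A condenser annulus displayed on a transmissive
LCD can be translated in the opposite direction to restore the overlap.

`apc.synthetic.MeniscusModel` encodes this with three parameters:

| parameter         | default | meaning                                             |
|-------------------|---------|-----------------------------------------------------|
| `shift_gain`      | 15 px/mm| pupil-image displacement per mm of radial position  |
| `well_radius`     | 8 mm    | well radius (24-well-plate scale)                   |
| `distortion_gain` | 0.02 /mm| ellipticity of the annulus image per mm of position |

plus rendering grays (`brightfield_gray` 220, `phase_gray` 60) and sensor
noise (`noise_sigma` 5, additive Gaussian). The gains are smooth-lens
surrogates — adequate for exercising the detection/compensation pipeline, not
a ray-traced meniscus.

## 2. Ring detection

Bertrand frames (default 1000×1000 px) are processed at a 20% **analysis
scale**: resize, CLAHE contrast equalization, fixed threshold, polarity
selection (bright band = annulus, dark band = phase ring), then contour
extraction. Candidate contours are filtered by:

* area bounds (`min_area` 500 px² at analysis scale),
* roundness `o = 4πA/P²` with `min_roundness` 0.7,
* rejection of contours touching the image border.

The surviving largest contour is fitted with a Taubin-style algebraic conic
(generalized eigenproblem), preceded by a convex-hull pass so that partial
occlusion of the band (e.g. by the pupil edge or a crossing dark band) does
not bias the fit. Centers are mapped between scales with the pixel-center
convention `x_analysis = (x_full + 0.5)·s − 0.5`.

The phase ring is only segmentable when it is not covered by the bright
annulus band; operationally its center is measured once from a *white-screen*
frame (LCD fully transmissive) and cached, matching how an instrument would
calibrate. `detect_offset` accepts that cached center.

**Numerical choices.** Marching-squares contours have a staircase bias that
inflates perimeters by ≈ 5% and depresses roundness; contours are therefore
simplified with Douglas–Peucker (tolerance 0.8 px) before computing `A`, `P`
and `o`. This makes discrete circles score 0.98–1.0 and squares exactly π/4.

**Benchmark.** `run_benchmark` renders `n` frames with per-axis offsets
uniform in ±`offset_range` (default 60 px), axis ratios in [0.9, 1], up to 3
specular-reflection distractor discs, and noise σ = 5, then reports error
statistics against ground truth at the analysis scale. The acceptance margin
is 15 px; measured medians are ≈ 0.15 px.

## 3. Offset-to-LCD calibration

The LCD translation `p` (mm) needed to cancel a pupil offset `Δd` (px) is
modeled per axis as `p = k·Δd + p0` with one shared slope `k` and per-axis
intercepts. `fit_calibration` solves the joint least-squares problem; when a
zero-offset pair is present the intercept is taken from it exactly and the
slope pooled through the origin. Underdetermined systems and non-positive
slopes raise `CalibrationError`. Typical `k` for the modeled optical train is
0.0113 mm/px; with 20 pairs, 2 px offset noise and 0.1 mm position noise the
slope is recovered within a few percent.

## 4. Confluent-area quantification

Full-well mosaics are quantified with thresholds **relative to the image's
own grays**: `g_ph` is the mean of a 5×5 patch at the well center (phase
background), `g_br` the top-decile gray of the center row (rim brightfield),
and

```
t_lower, t_upper = g_ph ± 0.15 (g_br − g_ph).
```

Worked example: `g_ph = 50`, `g_br = 250` gives thresholds (20, 80). Pixels
in `[t_lower, t_upper]` of the blurred mosaic are kept, eroded/dilated with a
disk (radius 2% of the well radius), restricted to the largest connected
component containing the well center, intersected with the well disc, and the
fraction reported relative to the disc area.

**Numerical choices.** Mosaics larger than `max_side` (2000 px) are
downscaled first; the smoothing sigma scales with the well radius
(`max(4, 0.008·R)` px) so that recovery is resolution-independent. Contrast
below 10 gray levels raises `DegenerateContrastError` rather than returning a
meaningless mask.

**Synthetic ground truth.** `generate_well_mosaic` builds a dark central
phase-contrast zone of prescribed area fraction surrounded by a bright rim,
with a logistic radial ramp between them and optional cell-like texture. The
ramp is positioned so that the upper relative threshold crosses exactly at
the ground-truth boundary radius — i.e. the generator's "truth" is defined in
the same brightness terms the measurement uses, which is what makes fraction
recovery a well-posed oracle. Recovery on textured 2000 px mosaics is within
~1 percentage point at both 41.9% and 5.0% truth.

## 5. Alignment metrics and sweeps

`apc.metrics` provides Tenengrad sharpness (mean squared Sobel gradient
magnitude) and mean gray. Over a simulated sweep that displaces the LCD
annulus from the compensated position, sharpness is maximal and mean gray
minimal at zero displacement, and the two series anti-correlate strongly
(Pearson r ≤ −0.9; typically ≈ −0.99).

## 6. Acquisition planning

`apc.acquire` plans a minimal centered rectangular tile grid (pitch =
`fov − overlap`) pruned to tiles intersecting the well disc; interpolates
focus with a least-squares plane through ≥ 3 anchor points (exact for
coplanar anchors, default anchors at half-radius on the ±x/±y axes); and
assembles tiles into a mosaic at their **known** grid coordinates with
optional shading-reference division, overlap-mean brightness matching and
linear feathering. Cross-correlation stitching is deliberately out of scope:
on a calibrated stage the coordinates are known, and on low-texture wells
correlation is unreliable.

## 7. Limitations

* The meniscus model is a first-order (linear shift, linear ellipticity)
  surrogate, not wave-optical or ray-traced; absolute gains are plausible
  rather than derived from lens data.
* Synthetic textures are Gaussian blobs, not cells; segmentation performance
  on real cultures will differ.
* Area ground truth is brightness-defined (see §4); biological confluence
  defined morphologically could diverge from it.
* The calibration model is affine and isotropic in slope; strong optical
  distortion would need a per-axis or nonlinear map.
* Mosaic assembly assumes uniform tile shape and accurate stage coordinates.
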