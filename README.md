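# apc — adaptive phase-contrast annulus compensation

Tools for compensating the **meniscus effect** in phase-contrast microscopy of
multiwell plates, built around a programmable transmissive-LCD condenser
annulus.

## The problem

Phase contrast requires the image of the condenser annulus to coincide with
the objective's phase ring in the back focal plane. In a multiwell plate the
liquid surface forms a meniscus that acts as a weak lens: away from the well
center, the annulus image is displaced radially and the phase-contrast effect
degrades — the background brightens, halos appear and fine structure washes
out. With a fixed glass annulus this limits usable imaging to a small region
near the well center.

If the condenser annulus is displayed on a transmissive LCD instead, it can be
translated electronically to re-center the annulus image for every field of
view. That requires three ingredients, all provided here:

1. **Ring detection** (`apc.detect`): segment the annulus image and the phase
   ring in a Bertrand-lens camera frame and measure their center offset
   `Δd` in pixels. Frames are downscaled to 20%, contrast-equalized (CLAHE),
   thresholded, and candidate contours are filtered by area and roundness

   ```
   o = 4πA / P²          (1 for a circle, π/4 for a square)
   ```

   before an algebraic (Taubin-style) ellipse fit yields the center.

2. **Calibration** (`apc.calibrate`): a linear map from camera-pixel offset to
   LCD annulus position in millimetres,

   ```
   p = k · Δd + p0
   ```

   fitted by least squares from (offset, position) pairs. A typical optical
   train gives `k ≈ 0.0113 mm/px`.

3. **Area quantification** (`apc.area`): confluent-area measurement on
   full-well mosaics using relative thresholds anchored to the image's own
   gray levels,

   ```
   t = g_ph ± 0.15 (g_br − g_ph)
   ```

   where `g_ph` is the phase-contrast background gray at the well center and
   `g_br` the brightfield-like gray near the rim. Pixels between the
   thresholds, cleaned up morphologically and restricted to the largest
   central component inside the well disc, form the confluent-area mask.

Supporting modules: `apc.synthetic` (a forward model of the meniscus effect
that renders Bertrand frames, calibration pairs, full-well mosaics and
displacement sweeps with known ground truth), `apc.metrics` (Tenengrad
sharpness and mean gray for alignment sweeps), `apc.acquire` (tile planning,
plane-interpolated autofocus, known-coordinate mosaic assembly) and `apc.io`.

## Quick example

```python
from apc import synthetic, detect, calibrate

# render a Bertrand frame with the annulus displaced (30, -12) px
truth = synthetic.concentric_truth(offset=(30.0, -12.0))
img, truth = synthetic.generate_bertrand_image(truth, synthetic.MeniscusModel(), seed=0)

# measure the annulus/phase-ring offset (phase-ring center cached from a
# white-screen calibration frame)
off = detect.detect_offset(img, phase_ring_center=(99.5, 99.5))
print(off.delta_d_full_resolution)   # ~ (30, -12)

# map it to an LCD translation
model = calibrate.CalibrationModel(k=0.0113, p0=(0.0, 0.0))
print(calibrate.map_offset_to_lcd(off, model, full_resolution=True))  # ~ (0.34, -0.14) mm
```

The same pipeline is available on the command line via the `apc` entry point:
`apc simulate bertrand`, `apc detect`, `apc calibrate`, `apc map`,
`apc quantify`, `apc benchmark`, `apc plan`, … (see `apc --help`).

## Performance on synthetic ground truth

Running the built-in benchmark (500 Bertrand frames, offsets up to 60 px per
axis, up to 3 specular-reflection distractors, Gaussian noise σ = 5) gives a
median center-localization error of ≈ 0.16 px at the 20% analysis scale —
far inside the 15 px margin at which compensation is still considered
successful. On textured synthetic full-well mosaics, area quantification
recovers a 41.9% ground-truth confluent fraction as ≈ 41.6% and a 5.0%
fraction as ≈ 4.9%.

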