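"""Synthetic optics simulator: Bertrand-lens pupil images, calibration pairs
and full-well mosaics with known ground truth.

The meniscus in a microtiter-plate well tilts the liquid surface away from the
well center, refracting the illumination so that the image of the condenser
annulus in the objective back focal plane is displaced (and mildly distorted)
relative to the phase ring. No physical ray tracing is attempted here; the
module implements a phenomenological model that is monotone in radial distance
and linear by default, which is all the downstream detection, calibration and
quantification algorithms assume. Every generator is fully seeded and returns
its ground truth so the whole pipeline can be benchmarked without hardware.

Pixel convention: origin at the top-left corner, x to the right, y downward,
integer pixel centers. Images are 8-bit grayscale ``numpy.uint8`` arrays
indexed ``[y, x]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class MeniscusModel:
    """Phenomenological meniscus model driving all synthetic images.

    Parameters
    ----------
    shift_gain
        Annulus displacement in Bertrand-image pixels per millimetre of radial
        distance of the imaged field from the well center. The displacement is
        directed radially outward and linear in radial distance.
    well_radius
        Well radius in millimetres (an MTP-24 well is ~8 mm radius).
    distortion_gain
        Reduction of the annulus ellipse axis ratio per millimetre of radial
        distance; the concave meniscus squeezes the annulus image into an
        ellipse near the well edge.
    brightfield_gray, phase_gray
        Background gray levels of a specimen image under brightfield
        conditions (rings not overlapping) and phase-contrast conditions
        (rings overlapping), 0-255.
    noise_sigma
        Standard deviation of additive Gaussian pixel noise, in gray levels.
    """

    shift_gain: float = 15.0
    well_radius: float = 8.0
    distortion_gain: float = 0.02
    brightfield_gray: int = 220
    phase_gray: int = 60
    noise_sigma: float = 5.0

    def __post_init__(self) -> None:
        if not (0 <= self.phase_gray < self.brightfield_gray <= 255):
            raise ValueError("require 0 <= phase_gray < brightfield_gray <= 255")
        if self.well_radius <= 0:
            raise ValueError("well_radius must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    def annulus_shift(self, position_mm: tuple[float, float]) -> np.ndarray:
        """Annulus displacement (px) for a field at ``position_mm`` relative
        to the well center. Zero at the center, radially outward, linear in
        radial distance."""
        pos = np.asarray(position_mm, dtype=float)
        r = float(np.hypot(*pos))
        if r == 0.0:
            return np.zeros(2)
        return self.shift_gain * pos  # == shift_gain * r * unit_vector

    def axis_ratio(self, position_mm: tuple[float, float]) -> float:
        """Annulus ellipse axis ratio (minor/major) at a field position."""
        r = float(np.hypot(*np.asarray(position_mm, dtype=float)))
        return float(np.clip(1.0 - self.distortion_gain * r, 0.2, 1.0))


@dataclass(frozen=True)
class BertrandGroundTruth:
    """Ground truth attached to one synthetic Bertrand-lens image."""

    phase_ring_center: tuple[float, float]
    annulus_center: tuple[float, float]
    annulus_radii: tuple[float, float]  # (inner, outer) px along major axis
    axis_ratio: float = 1.0
    incomplete: bool = False  # annulus partially outside the frame

    def __post_init__(self) -> None:
        r_in, r_out = self.annulus_radii
        if not r_in < r_out:
            raise ValueError("inner radius must be smaller than outer radius")
        if not 0.0 < self.axis_ratio <= 1.0:
            raise ValueError("axis_ratio must be in (0, 1]")

    @property
    def offset(self) -> tuple[float, float]:
        """Annulus center minus phase-ring center, in pixels."""
        return (
            self.annulus_center[0] - self.phase_ring_center[0],
            self.annulus_center[1] - self.phase_ring_center[1],
        )


@dataclass(frozen=True)
class WellGroundTruth:
    """Ground truth for one synthetic full-well mosaic."""

    mosaic_size: tuple[int, int]  # (width, height) px
    well_center: tuple[float, float]
    well_radius: float  # px
    phase_mask: np.ndarray = field(repr=False)  # bool image, [y, x]
    true_fraction: float = 0.0

    def recompute_fraction(self) -> float:
        """Pixel-count oracle: set pixels inside the well circle over the
        analytic well area."""
        h, w = self.phase_mask.shape
        yy, xx = np.mgrid[0:h, 0:w]
        inside = (xx - self.well_center[0]) ** 2 + (
            yy - self.well_center[1]
        ) ** 2 <= self.well_radius**2
        return float(np.count_nonzero(self.phase_mask & inside)) / (
            np.pi * self.well_radius**2
        )


# --------------------------------------------------------------------------- #
# rendering primitives
# --------------------------------------------------------------------------- #

_EDGE_SOFTNESS = 2.0  # px; erf edge width of all rendered ring bands


def _soft_band(
    shape: tuple[int, int],
    center: tuple[float, float],
    r_inner: float,
    r_outer: float,
    axis_ratio: float = 1.0,
    softness: float = _EDGE_SOFTNESS,
) -> np.ndarray:
    """Soft-edged elliptical band membership weight in [0, 1].

    The band is an ellipse with semi-major axis along x; the normalized
    radius of a pixel is ``sqrt(dx^2 + (dy/axis_ratio)^2)`` and the band
    covers normalized radii in [r_inner, r_outer] with error-function edges.
    """
    h, w = shape
    # evaluate only inside the band's bounding box; the weight is ~0 outside
    pad = 6.0 * softness
    xa = max(0, int(center[0] - r_outer - pad))
    xb = min(w, int(center[0] + r_outer + pad) + 1)
    ya = max(0, int(center[1] - r_outer * axis_ratio - pad))
    yb = min(h, int(center[1] + r_outer * axis_ratio + pad) + 1)
    out = np.zeros(shape)
    if xa >= xb or ya >= yb:
        return out
    yy, xx = np.mgrid[ya:yb, xa:xb].astype(float)
    dx = xx - center[0]
    dy = (yy - center[1]) / axis_ratio
    u = np.hypot(dx, dy)
    s = softness * np.sqrt(2.0)
    w_in = 0.5 * (1.0 + special.erf((u - r_inner) / s))
    w_out = 0.5 * (1.0 + special.erf((r_outer - u) / s))
    out[ya:yb, xa:xb] = w_in * w_out
    return out


def _to_uint8(img: np.ndarray, noise_sigma: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


# --------------------------------------------------------------------------- #
# Bertrand-lens images
# --------------------------------------------------------------------------- #

#: default frame for synthetic Bertrand images, px (width, height)
BERTRAND_SIZE = (1000, 1000)
#: default annulus band radii, px (inner, outer)
ANNULUS_RADII = (260.0, 300.0)
#: extra half-width of the (dark) phase-ring band beyond the annulus band, px
PHASE_RING_MARGIN = 12.0
#: pupil background gray between/outside the rings
_PUPIL_GRAY = 140.0
#: brightness of the transmissive annulus band
_ANNULUS_GRAY = 235.0


def generate_bertrand_image(
    truth: BertrandGroundTruth,
    model: MeniscusModel,
    distractors: int = 0,
    seed: int = 0,
    size: tuple[int, int] = BERTRAND_SIZE,
    draw_annulus: bool = True,
    dimming: float = 0.0,
) -> tuple[np.ndarray, BertrandGroundTruth]:
    """Render one Bertrand-lens pupil image.

    The phase ring appears as a dark band on the pupil background; the
    condenser annulus as a bright elliptical band at ``truth.annulus_center``
    with the requested axis ratio. ``distractors`` bright discs (radius
    5-15 px) are placed outside the annulus to emulate reflections.
    ``draw_annulus=False`` emulates the white-screen calibration image that
    shows only the phase ring. ``dimming`` in [0, 1) attenuates the annulus
    band where it overlaps the phase ring.

    Returns the 8-bit image and the ground truth (flagged ``incomplete`` when
    the annulus extends past the frame).
    """
    w, h = size
    if w <= 0 or h <= 0:
        raise ValueError("image dimensions must be positive")
    r_in, r_out = truth.annulus_radii
    rng = np.random.default_rng(seed)

    # incomplete-ring flag: the annulus ellipse bounding box vs the frame
    cx, cy = truth.annulus_center
    if (
        cx - r_out < 0
        or cx + r_out > w - 1
        or cy - r_out * truth.axis_ratio < 0
        or cy + r_out * truth.axis_ratio > h - 1
    ):
        truth = replace(truth, incomplete=True)

    img = np.full((h, w), _PUPIL_GRAY, dtype=float)

    # dark phase ring: a circular band slightly wider than the annulus band
    w_ph = _soft_band(
        (h, w),
        truth.phase_ring_center,
        r_in - PHASE_RING_MARGIN,
        r_out + PHASE_RING_MARGIN,
    )
    img = img * (1.0 - w_ph) + model.phase_gray * w_ph

    if draw_annulus:
        w_an = _soft_band(
            (h, w), truth.annulus_center, r_in, r_out, truth.axis_ratio
        )
        gray = _ANNULUS_GRAY * (1.0 - dimming * w_ph)
        img = img * (1.0 - w_an) + gray * w_an

    # reflection distractors: bright discs outside the annulus band
    placed = 0
    attempts = 0
    while placed < distractors and attempts < 200:
        attempts += 1
        radius = rng.uniform(5.0, 15.0)
        px = rng.uniform(radius, w - 1 - radius)
        py = rng.uniform(radius, h - 1 - radius)
        dx = px - truth.annulus_center[0]
        dy = (py - truth.annulus_center[1]) / truth.axis_ratio
        u = np.hypot(dx, dy)
        # strictly outside (or well inside) the annulus band
        if r_in - 2 * radius - 10 < u < r_out + 2 * radius + 10:
            continue
        w_d = _soft_band((h, w), (px, py), -radius, radius, softness=1.0)
        img = img * (1.0 - w_d) + _ANNULUS_GRAY * w_d
        placed += 1

    return _to_uint8(img, model.noise_sigma, rng), truth


def concentric_truth(
    center: tuple[float, float] | None = None,
    offset: tuple[float, float] = (0.0, 0.0),
    axis_ratio: float = 1.0,
    size: tuple[int, int] = BERTRAND_SIZE,
    radii: tuple[float, float] = ANNULUS_RADII,
) -> BertrandGroundTruth:
    """Convenience constructor: phase ring at the frame center (or ``center``)
    and the annulus displaced by ``offset`` pixels."""
    if center is None:
        center = ((size[0] - 1) / 2.0, (size[1] - 1) / 2.0)
    return BertrandGroundTruth(
        phase_ring_center=center,
        annulus_center=(center[0] + offset[0], center[1] + offset[1]),
        annulus_radii=radii,
        axis_ratio=axis_ratio,
    )


# --------------------------------------------------------------------------- #
# calibration pairs
# --------------------------------------------------------------------------- #


def generate_calibration_pairs(
    k_true: float,
    p0_true: tuple[float, float],
    n: int,
    noise_sigma_d: float = 0.0,
    noise_sigma_p: float = 0.0,
    seed: int = 0,
    offset_range: float = 100.0,
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Generate ``n`` (offset px, LCD position mm) calibration pairs.

    Before noise each pair satisfies ``p = k_true * d + p0_true``. Offsets are
    drawn uniformly in [-offset_range, offset_range] per axis; the first pair
    is placed at zero offset so the default position is directly observed.
    Gaussian noise of ``noise_sigma_d`` px and ``noise_sigma_p`` mm is added
    independently to every coordinate.
    """
    if n < 2:
        raise ValueError("need at least 2 calibration pairs")
    rng = np.random.default_rng(seed)
    d = rng.uniform(-offset_range, offset_range, size=(n, 2))
    d[0] = 0.0
    p = k_true * d + np.asarray(p0_true, dtype=float)
    d = d + rng.normal(0.0, noise_sigma_d, size=d.shape)
    p = p + rng.normal(0.0, noise_sigma_p, size=p.shape)
    return [((float(di[0]), float(di[1])), (float(pi[0]), float(pi[1]))) for di, pi in zip(d, p)]


# --------------------------------------------------------------------------- #
# full-well mosaics
# --------------------------------------------------------------------------- #

#: default synthetic mosaic edge length, px
MOSAIC_SIZE = 2000
#: logistic ramp scale as a fraction of the well radius; the 10-90% width of
#: the phase->brightfield transition is ~4.4x this
_RAMP_SCALE = 0.0125
#: Eq-3 relative threshold level; the ground-truth phase boundary is defined
#: as the radius where the ramp crosses g_ph + this fraction of (g_br - g_ph)
_THRESHOLD_LEVEL = 0.15


def generate_well_mosaic(
    truth_fraction: float,
    model: MeniscusModel,
    texture: bool = False,
    seed: int = 0,
    size: int = MOSAIC_SIZE,
) -> tuple[np.ndarray, WellGroundTruth]:
    """Render a full-well mosaic with a centered phase-contrast disc.

    Inside a central disc covering ``truth_fraction`` of the well area the
    background sits near ``model.phase_gray``; outside it the background
    ramps logistically up to ``model.brightfield_gray``, emulating the slow
    fall and rapid brightening observed moving out of the aligned region.
    The ramp is positioned so that the brightness crosses the 15% relative
    threshold exactly at the ground-truth disc boundary: phase-contrast
    conditions are *defined* by that brightness criterion, so the ground
    truth uses the same definition. Corners outside the well circle are
    brightfield gray. ``texture`` overlays cell-like dark/bright elliptical
    speckle in both regions.
    """
    if not 0.0 < truth_fraction <= 1.0:
        raise ValueError("truth_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    h = w = int(size)
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    well_radius = 0.48 * size
    r_phase = well_radius * np.sqrt(truth_fraction)

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    rr = np.hypot(xx - center[0], yy - center[1])

    g_ph = float(model.phase_gray)
    g_br = float(model.brightfield_gray)
    s = _RAMP_SCALE * well_radius
    # place the logistic so its _THRESHOLD_LEVEL crossing sits at r_phase
    r_mid = r_phase + s * np.log((1.0 - _THRESHOLD_LEVEL) / _THRESHOLD_LEVEL)
    ramp = 1.0 / (1.0 + np.exp(-np.clip((rr - r_mid) / s, -60, 60)))
    img = g_ph + (g_br - g_ph) * ramp

    if texture:
        img += _cell_texture((h, w), rng)

    # outside the well circle: brightfield
    outside = rr > well_radius
    img[outside] = g_br

    mask = (rr <= r_phase) & ~outside
    truth = WellGroundTruth(
        mosaic_size=(w, h),
        well_center=center,
        well_radius=well_radius,
        phase_mask=mask,
        true_fraction=float(np.count_nonzero(mask)) / (np.pi * well_radius**2),
    )
    return _to_uint8(img, model.noise_sigma, rng), truth


def _cell_texture(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Sparse cell-like speckle: small anisotropic Gaussian bumps, half dark
    (cell bodies) and half bright (halos), amplitude ~20 gray levels."""
    h, w = shape
    n_cells = int(h * w / 4000)
    tex = np.zeros(shape)
    cy = rng.uniform(0, h, n_cells)
    cx = rng.uniform(0, w, n_cells)
    amp = rng.choice([-1.0, 1.0], n_cells) * rng.uniform(10, 25, n_cells)
    sig = rng.uniform(3, 9, n_cells)
    # render on a coarse additive canvas; local windows keep this cheap
    for x0, y0, a, sg in zip(cx, cy, amp, sig):
        r = int(3 * sg)
        xa, xb = int(max(0, x0 - r)), int(min(w, x0 + r + 1))
        ya, yb = int(max(0, y0 - r)), int(min(h, y0 + r + 1))
        if xa >= xb or ya >= yb:
            continue
        gy, gx = np.mgrid[ya:yb, xa:xb].astype(float)
        tex[ya:yb, xa:xb] += a * np.exp(
            -((gx - x0) ** 2 + (gy - y0) ** 2) / (2 * sg**2)
        )
    return tex


# --------------------------------------------------------------------------- #
# displacement sweep
# --------------------------------------------------------------------------- #

#: px of Bertrand-image annulus displacement per mm of LCD shift (1/k with the
#: calibration slope k = 0.0113 mm/px)
LCD_PX_PER_MM = 1.0 / 0.0113


def _band_overlap_fraction(
    offset: float, r_in: float, r_out: float, margin: float
) -> float:
    """Fraction of the annulus band area that lands on the phase-ring band,
    by dense polar sampling (cheap, exact enough for a brightness law)."""
    theta = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    radii = np.linspace(r_in, r_out, 24)
    tt, uu = np.meshgrid(theta, radii)
    x = uu * np.cos(tt) + offset
    y = uu * np.sin(tt)
    rho = np.hypot(x, y)
    on_ring = (rho >= r_in - margin) & (rho <= r_out + margin)
    # weight by radius (polar area element)
    return float(np.sum(on_ring * uu) / np.sum(uu))


def simulate_displacement_sweep(
    model: MeniscusModel,
    shift_steps: list[float],
    seed: int = 0,
    specimen_size: tuple[int, int] = (400, 400),
    bertrand_size: tuple[int, int] = BERTRAND_SIZE,
) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """Simulate shifting the LCD annulus away from alignment in steps.

    For each shift (mm on the LCD) the annulus image moves by
    ``shift * LCD_PX_PER_MM`` pixels. The specimen image's background rises
    from ``phase_gray`` toward ``brightfield_gray`` and its feature contrast
    falls as the annulus/phase-ring band overlap is lost; at zero shift the
    specimen has minimum mean gray and maximum contrast.

    Returns a list of (shift mm, specimen image, bertrand image).
    """
    if not shift_steps:
        raise ValueError("shift list must be non-empty")
    r_in, r_out = ANNULUS_RADII
    rng = np.random.default_rng(seed)
    out: list[tuple[float, np.ndarray, np.ndarray]] = []
    base_seed = int(rng.integers(0, 2**31 - 1))
    for i, shift in enumerate(shift_steps):
        offset_px = shift * LCD_PX_PER_MM
        truth = concentric_truth(offset=(offset_px, 0.0), size=bertrand_size)
        bertrand, _ = generate_bertrand_image(
            truth, model, seed=base_seed + 2 * i, size=bertrand_size
        )
        f = _band_overlap_fraction(offset_px, r_in, r_out, PHASE_RING_MARGIN)
        specimen = _specimen_image(
            specimen_size, model, overlap=f, rng=np.random.default_rng(base_seed + 2 * i + 1)
        )
        out.append((float(shift), specimen, bertrand))
    return out


def _specimen_image(
    size: tuple[int, int],
    model: MeniscusModel,
    overlap: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Specimen image whose background and contrast follow the band overlap.

    Background gray interpolates linearly between brightfield (overlap 0) and
    phase gray (overlap 1); the fixed cell texture is scaled by the overlap so
    edge contrast falls as phase contrast is lost.
    """
    w, h = size
    bg = model.brightfield_gray + (model.phase_gray - model.brightfield_gray) * overlap
    # fixed texture pattern (independent of overlap) so only contrast scales
    tex_rng = np.random.default_rng(12345)
    tex = _cell_texture((h, w), tex_rng)
    img = bg + (0.2 + 0.8 * overlap) * 2.5 * tex
    return _to_uint8(img, model.noise_sigma, rng)
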