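"""Ring detection in Bertrand-lens images.

Locates the condenser annulus (bright band) and the phase ring (dark band) in
a pupil image and reports their center offset. Pipeline per ring: downscale ->
CLAHE -> binary threshold -> outer-contour extraction with size/roundness
filters -> convex hull -> algebraic ellipse fit. The offset drives the LCD
annulus correction (see :mod:`apc.calibrate`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull
from skimage import exposure, measure, transform


class RingDetectionError(RuntimeError):
    """Raised when a ring cannot be segmented, found or fitted."""


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class ContourStats:
    """Area, perimeter and roundness of one contour.

    Roundness ``o = 4*pi*A / P**2`` equals 1 for a circle and decreases for
    elongated or irregular shapes; it is the filter that rejects reflections.
    """

    area: float  # px^2
    perimeter: float  # px
    roundness: float

    @staticmethod
    def from_polygon(poly: np.ndarray, simplify: float = 0.8) -> "ContourStats":
        """Compute stats from an (N, 2) polygon in (x, y) order.

        The polygon is Douglas-Peucker simplified (tolerance ``simplify`` px)
        first: marching-squares contours of binary masks carry a staircase
        that inflates the perimeter by ~5% and would bias the roundness of a
        true circle well below 1.
        """
        if simplify > 0 and len(poly) > 4:
            poly = measure.approximate_polygon(np.ascontiguousarray(poly), tolerance=simplify)
        a = _shoelace_area(poly)
        p = _polyline_length(poly, closed=True)
        return ContourStats(area=a, perimeter=p, roundness=4.0 * np.pi * a / p**2)


@dataclass(frozen=True)
class RingFit:
    """Fitted ellipse for one detected ring, at the analysis scale."""

    center: tuple[float, float]  # (x, y) px at analysis scale
    semi_major: float
    semi_minor: float
    orientation: float  # radians, major axis vs +x
    stats: ContourStats
    scale: float = 1.0  # analysis downscale factor

    @property
    def center_full_resolution(self) -> tuple[float, float]:
        return (
            from_analysis_scale(self.center[0], self.scale),
            from_analysis_scale(self.center[1], self.scale),
        )


@dataclass(frozen=True)
class RingOffset:
    """Annulus center minus phase-ring center, at the analysis scale."""

    delta_d: tuple[float, float]
    scale: float = 1.0

    @property
    def delta_d_full_resolution(self) -> tuple[float, float]:
        return (self.delta_d[0] / self.scale, self.delta_d[1] / self.scale)

    @property
    def magnitude(self) -> float:
        return float(np.hypot(*self.delta_d))


@dataclass(frozen=True)
class DetectorParams:
    """Tunable detection parameters for one ring.

    The annulus (bright on darker pupil) and the phase ring (dark on bright)
    use distinct parameter sets; ``polarity`` selects whether the image is
    inverted before thresholding so both share one code path. ``clahe_clip``
    is the contrast-limited adaptive histogram equalization clip limit as a
    fraction in (0, 1] (set to 0 to disable CLAHE); ``clahe_tiles`` is the
    number of tiles per image side. Areas are in analysis-scale px^2.
    """

    downscale: float = 0.2
    clahe_clip: float = 0.01
    clahe_tiles: int = 8
    binary_threshold: int = 128
    min_area: float = 500.0
    max_area: float = 1e7
    min_roundness: float = 0.7
    polarity: str = "bright-ring"  # or "dark-ring"

    def __post_init__(self) -> None:
        if not 0.0 < self.downscale <= 1.0:
            raise ValueError("downscale must be in (0, 1]")
        if not self.min_area < self.max_area:
            raise ValueError("min_area must be below max_area")
        if not 0.0 < self.min_roundness <= 1.0:
            raise ValueError("min_roundness must be in (0, 1]")
        if self.polarity not in ("bright-ring", "dark-ring"):
            raise ValueError("polarity must be 'bright-ring' or 'dark-ring'")


#: defaults for the bright condenser annulus
ANNULUS_PARAMS = DetectorParams(polarity="bright-ring", binary_threshold=160)
#: defaults for the dark phase ring (inverted before thresholding)
PHASE_RING_PARAMS = DetectorParams(polarity="dark-ring", binary_threshold=160)


def load_params(path: str | Path) -> dict[str, DetectorParams]:
    """Read named DetectorParams blocks (``annulus``, ``phase_ring``) from a
    JSON config file."""
    blocks = json.loads(Path(path).read_text())
    return {name: DetectorParams(**kw) for name, kw in blocks.items()}


# --------------------------------------------------------------------------- #
# coordinate helpers
# --------------------------------------------------------------------------- #


def to_analysis_scale(coord: float, scale: float) -> float:
    """Map a full-resolution pixel coordinate to the analysis scale.

    With integer pixel centers, downscaling by ``scale`` maps the center of
    pixel x to ``(x + 0.5) * scale - 0.5`` (pixel areas, not indices, are
    rescaled). Offsets between two coordinates scale by the plain factor.
    """
    return (coord + 0.5) * scale - 0.5


def from_analysis_scale(coord: float, scale: float) -> float:
    return (coord + 0.5) / scale - 0.5


# --------------------------------------------------------------------------- #
# polygon helpers
# --------------------------------------------------------------------------- #


def _shoelace_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def _polyline_length(poly: np.ndarray, closed: bool = True) -> float:
    pts = np.vstack([poly, poly[:1]]) if closed else poly
    return float(np.sum(np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1]))))


# --------------------------------------------------------------------------- #
# pipeline stages
# --------------------------------------------------------------------------- #


def preprocess(image: np.ndarray, params: DetectorParams) -> np.ndarray:
    """Downscale and contrast-equalize an 8-bit grayscale image.

    Returns an 8-bit image of dimensions ``floor(downscale * original)``.
    CLAHE is skipped when ``clahe_clip == 0`` or the image is constant (there
    is no structure to equalize).
    """
    if image.size == 0:
        raise ValueError("empty image")
    img = np.asarray(image)
    if params.downscale < 1.0:
        h = int(img.shape[0] * params.downscale)
        w = int(img.shape[1] * params.downscale)
        if min(h, w) < 16:
            raise ValueError("downscaled image smaller than 16 px")
        img = transform.resize(
            img.astype(float) / 255.0, (h, w), anti_aliasing=True
        )
    else:
        img = img.astype(float) / 255.0
    if params.clahe_clip > 0 and img.max() > img.min():
        kernel = max(8, min(img.shape) // params.clahe_tiles)
        img = exposure.equalize_adapthist(
            img, kernel_size=kernel, clip_limit=params.clahe_clip
        )
    return np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)


def segment_ring(image: np.ndarray, params: DetectorParams) -> np.ndarray:
    """Binary threshold isolating the ring band.

    ``dark-ring`` polarity inverts the image first so the dark phase ring and
    the bright annulus share the same foreground convention.
    """
    img = np.asarray(image)
    if params.polarity == "dark-ring":
        img = 255 - img
    mask = img > params.binary_threshold
    n = int(np.count_nonzero(mask))
    if n == 0 or n == mask.size:
        raise RingDetectionError("no segmentation: threshold yields empty or full mask")
    return mask


def find_ring_contour(
    mask: np.ndarray, params: DetectorParams
) -> tuple[np.ndarray, ContourStats]:
    """Extract the outer contour of the ring from a binary mask.

    Outer contours are traced at sub-pixel precision on the mask; each is
    screened by area and roundness (``o = 4*pi*A/P**2``) to reject reflections
    and noise; among survivors the largest-area contour wins (the true ring is
    the dominant structure). Returns the contour as an (N, 2) array of (x, y)
    points plus its stats.
    """
    if not mask.any():
        raise RingDetectionError("no ring found: empty mask")
    # pad so bands touching the frame still close into polygons
    padded = np.pad(mask, 1, mode="constant")
    contours = measure.find_contours(padded.astype(float), 0.5)
    best: tuple[float, np.ndarray, ContourStats] | None = None
    h, w = mask.shape
    for c in contours:
        if len(c) < 5:
            continue
        poly = c[:, ::-1] - 1.0  # (row, col) -> (x, y), undo padding
        # a contour hugging the frame border is a background artifact (or a
        # ring that extends past the frame), not a complete ring
        if (
            poly[:, 0].min() < 0.0
            or poly[:, 1].min() < 0.0
            or poly[:, 0].max() > w - 1.0
            or poly[:, 1].max() > h - 1.0
        ):
            continue
        stats = ContourStats.from_polygon(poly)
        if not (params.min_area <= stats.area <= params.max_area):
            continue
        if stats.roundness < params.min_roundness:
            continue
        if best is None or stats.area > best[0]:
            best = (stats.area, poly, stats)
    if best is None:
        raise RingDetectionError("no ring found: no contour passes size/roundness filters")
    # keep only the outer contour: inner hole contours of the same band have
    # smaller area, so the largest-area survivor is the outer edge
    return best[1], best[2]


def _taubin_conic(points: np.ndarray) -> np.ndarray:
    """Taubin's approximate mean-square conic fit.

    Minimizes the algebraic conic residual normalized by the mean squared
    gradient, via the generalized eigenproblem ``M v = mu N v`` on the design
    moments. Returns conic coefficients (a, b, c, d, e, f) for
    ``a x^2 + b x y + c y^2 + d x + e y + f = 0``.
    """
    x = points[:, 0].astype(float)
    y = points[:, 1].astype(float)
    mx, my = x.mean(), y.mean()
    sc = np.hypot(x - mx, y - my).mean() or 1.0
    u = (x - mx) / sc
    v = (y - my) / sc
    design = np.column_stack([u**2, u * v, v**2, u, v, np.ones_like(u)])
    m = design.T @ design / len(u)
    # gradient design: d/du and d/dv of each basis monomial
    gu = np.column_stack([2 * u, v, np.zeros_like(u), np.ones_like(u), np.zeros_like(u), np.zeros_like(u)])
    gv = np.column_stack([np.zeros_like(u), u, 2 * v, np.zeros_like(u), np.ones_like(u), np.zeros_like(u)])
    n = (gu.T @ gu + gv.T @ gv) / len(u)
    from scipy.linalg import eig

    w, vecs = eig(m, n)
    w = np.real(w)
    vecs = np.real(vecs)
    w[~np.isfinite(w)] = np.inf
    order = np.argsort(np.abs(w))
    conic = None
    for idx in order:
        cand = vecs[:, idx]
        # ellipse discriminant b^2 - 4ac < 0
        if cand[1] ** 2 - 4 * cand[0] * cand[2] < 0:
            conic = cand
            break
    if conic is None:
        raise RingDetectionError("fit failed: no elliptical solution")
    a, b, c, d, e, f = conic
    # undo normalization: substitute u = (x-mx)/sc, v = (y-my)/sc
    a2, b2, c2 = a / sc**2, b / sc**2, c / sc**2
    d2 = d / sc - 2 * a * mx / sc**2 - b * my / sc**2
    e2 = e / sc - 2 * c * my / sc**2 - b * mx / sc**2
    f2 = (
        f
        + a * mx**2 / sc**2
        + b * mx * my / sc**2
        + c * my**2 / sc**2
        - d * mx / sc
        - e * my / sc
    )
    return np.array([a2, b2, c2, d2, e2, f2])


def _conic_to_ellipse(conic: np.ndarray) -> tuple[tuple[float, float], float, float, float]:
    """Convert conic coefficients to (center, semi_major, semi_minor, theta)."""
    a, b, c, d, e, f = conic
    disc = b**2 - 4 * a * c
    if disc >= 0:
        raise RingDetectionError("fit failed: conic is not an ellipse")
    cx = (2 * c * d - b * e) / disc
    cy = (2 * a * e - b * d) / disc
    # evaluate conic at center to get the constant term of the centered form
    f0 = a * cx**2 + b * cx * cy + c * cy**2 + d * cx + e * cy + f
    # eigen-decompose the quadratic form [[a, b/2], [b/2, c]]
    q = np.array([[a, b / 2.0], [b / 2.0, c]])
    evals, evecs = np.linalg.eigh(q)
    if np.any(evals * -f0 <= 0):
        raise RingDetectionError("fit failed: degenerate ellipse")
    axes = np.sqrt(-f0 / evals)
    i_major = int(np.argmax(axes))
    theta = float(np.arctan2(evecs[1, i_major], evecs[0, i_major]))
    return (float(cx), float(cy)), float(axes.max()), float(axes.min()), theta


def fit_ellipse(contour: np.ndarray, scale: float = 1.0) -> RingFit:
    """Fit an ellipse to a contour's convex hull.

    The convex hull bridges gaps and bites in the contour (e.g. arcs dimmed by
    the phase ring) before the Taubin-style approximate mean-square fit.
    """
    pts = np.asarray(contour, dtype=float)
    if len(pts) < 5:
        raise RingDetectionError("fit failed: fewer than 5 contour points")
    try:
        hull = ConvexHull(pts)
        hull_pts = pts[hull.vertices]
    except Exception as exc:  # qhull raises on collinear input
        raise RingDetectionError(f"fit failed: degenerate hull ({exc})") from exc
    if len(hull_pts) < 5:
        raise RingDetectionError("fit failed: degenerate hull")
    stats = ContourStats.from_polygon(pts)
    conic = _taubin_conic(hull_pts)
    center, major, minor, theta = _conic_to_ellipse(conic)
    return RingFit(
        center=center,
        semi_major=major,
        semi_minor=minor,
        orientation=theta,
        stats=stats,
        scale=scale,
    )


def detect_ring(image: np.ndarray, params: DetectorParams) -> RingFit:
    """Full single-ring pipeline: preprocess, segment, contour, ellipse fit."""
    pre = preprocess(image, params)
    mask = segment_ring(pre, params)
    contour, _stats = find_ring_contour(mask, params)
    fit = fit_ellipse(contour, scale=params.downscale)
    return fit


def detect_offset(
    bertrand: np.ndarray,
    annulus_params: DetectorParams = ANNULUS_PARAMS,
    ring_params: DetectorParams = PHASE_RING_PARAMS,
    phase_ring_center: tuple[float, float] | None = None,
) -> RingOffset:
    """Offset of the condenser annulus relative to the phase ring.

    ``phase_ring_center`` (analysis-scale px), when supplied, is the cached
    center from the calibration image; otherwise the phase ring is detected
    from this image, which requires it to be segmentable (calibration-style
    image). Returns the offset at the analysis scale.
    """
    try:
        annulus = detect_ring(bertrand, annulus_params)
    except RingDetectionError as exc:
        raise RingDetectionError(f"annulus: {exc}") from exc
    if phase_ring_center is None:
        try:
            ring = detect_ring(bertrand, ring_params)
        except RingDetectionError as exc:
            raise RingDetectionError(f"phase ring: {exc}") from exc
        phase_ring_center = ring.center
    dd = (
        annulus.center[0] - phase_ring_center[0],
        annulus.center[1] - phase_ring_center[1],
    )
    if not np.all(np.isfinite(dd)):
        raise RingDetectionError("non-finite offset")
    return RingOffset(delta_d=dd, scale=annulus.scale)


# --------------------------------------------------------------------------- #
# benchmark
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class BenchmarkResult:
    """Center-detection error statistics over synthetic Bertrand images.

    Errors are Euclidean distances between detected and true annulus centers
    at the analysis scale, in pixels.
    """

    errors: np.ndarray = field(repr=False)
    margin: float
    n_failed: int = 0

    @property
    def median(self) -> float:
        return float(np.median(self.errors))

    @property
    def mean(self) -> float:
        return float(np.mean(self.errors))

    @property
    def std(self) -> float:
        return float(np.std(self.errors, ddof=1)) if len(self.errors) > 1 else 0.0

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.errors, q))

    @property
    def fraction_within_margin(self) -> float:
        return float(np.mean(self.errors <= self.margin))

    def summary(self) -> dict:
        return {
            "n": int(len(self.errors)),
            "n_failed": self.n_failed,
            "median_px": self.median,
            "mean_px": self.mean,
            "std_px": self.std,
            "p2.5_px": self.percentile(2.5),
            "p97.5_px": self.percentile(97.5),
            "margin_px": self.margin,
            "fraction_within_margin": self.fraction_within_margin,
        }


#: acceptance margin for phase-contrast-preserving misalignment, px at the
#: 20% analysis scale
ACCEPTANCE_MARGIN_PX = 15.0


def run_benchmark(
    n: int = 500,
    offset_range: float = 60.0,
    distractors: int = 3,
    seed: int = 0,
    noise_sigma: float = 5.0,
    annulus_params: DetectorParams = ANNULUS_PARAMS,
    margin: float = ACCEPTANCE_MARGIN_PX,
) -> BenchmarkResult:
    """Benchmark annulus-center detection on synthetic Bertrand images.

    Generates ``n`` images with per-axis offsets uniform in
    [-offset_range, offset_range] full-resolution px, up to ``distractors``
    reflection discs each, runs the detection pipeline and reports Euclidean
    center-error statistics at the analysis scale against ground truth.
    Detection failures count as errors at infinity.
    """
    from . import synthetic

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    model = synthetic.MeniscusModel(noise_sigma=noise_sigma)
    errors = []
    n_failed = 0
    records = []
    for i in range(n):
        off = rng.uniform(-offset_range, offset_range, size=2)
        ratio = rng.uniform(0.9, 1.0)
        k = int(rng.integers(0, distractors + 1))
        truth = synthetic.concentric_truth(offset=(off[0], off[1]), axis_ratio=ratio)
        img, truth = synthetic.generate_bertrand_image(
            truth, model, distractors=k, seed=int(rng.integers(0, 2**31 - 1))
        )
        try:
            fit = detect_ring(img, annulus_params)
        except RingDetectionError:
            n_failed += 1
            errors.append(np.inf)
            records.append((truth.annulus_center, None))
            continue
        true_scaled = (
            to_analysis_scale(truth.annulus_center[0], fit.scale),
            to_analysis_scale(truth.annulus_center[1], fit.scale),
        )
        err = float(np.hypot(fit.center[0] - true_scaled[0], fit.center[1] - true_scaled[1]))
        errors.append(err)
        records.append((truth.annulus_center, fit.center))
    return BenchmarkResult(errors=np.asarray(errors), margin=margin, n_failed=n_failed)
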