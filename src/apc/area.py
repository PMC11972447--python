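"""Quantification of the phase-contrast area in a full-well image.

Phase-contrast conditions show as a dark background around the well center;
brightness rises toward brightfield where the annulus/phase-ring overlap is
lost. The algorithm thresholds the blurred mosaic between relative bounds
derived from the center gray value g_ph and a brightfield estimate g_br,

    t_upper, t_lower = g_ph +/- 0.15 * (g_br - g_ph),

isolates the central connected patch morphologically, and reports its pixel
area over the analytic well area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import morphology, transform


class DegenerateContrastError(RuntimeError):
    """No phase/brightfield gray-level distinction exists in the image."""


#: Eq-3 relative threshold level around the center gray value
THRESHOLD_LEVEL = 0.15


@dataclass(frozen=True)
class ThresholdPair:
    """Relative phase-contrast thresholds derived from a well image."""

    g_ph: float  # gray value at the well/image center
    g_br: float  # brightfield gray estimate
    t_upper: float
    t_lower: float

    @staticmethod
    def from_grays(g_ph: float, g_br: float) -> "ThresholdPair":
        half = THRESHOLD_LEVEL * (g_br - g_ph)
        return ThresholdPair(
            g_ph=g_ph, g_br=g_br, t_upper=g_ph + half, t_lower=g_ph - half
        )


@dataclass(frozen=True)
class AreaResult:
    """Binary phase-contrast mask and area fraction for one well image."""

    mask: np.ndarray = field(repr=False)  # bool, at analysis scale
    fraction: float
    thresholds: ThresholdPair
    well_radius_px: float  # at analysis scale


def compute_thresholds(
    blurred: np.ndarray,
    quantile: float = 0.10,
    min_contrast: float = 10.0,
) -> ThresholdPair:
    """Derive the relative thresholds from a blurred well image.

    ``g_ph`` is the mean of the 5x5 neighborhood of the image center (the
    meniscus center, where phase contrast must hold); ``g_br`` is the mean of
    the top ``quantile`` fraction of gray values along the horizontal
    cross-section through the center, which samples brightfield pixels near
    the well edge.
    """
    img = np.asarray(blurred, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    h, w = img.shape
    cy, cx = h // 2, w // 2
    g_ph = float(img[max(0, cy - 2) : cy + 3, max(0, cx - 2) : cx + 3].mean())
    row = np.sort(img[cy, :])[::-1]
    k = max(1, int(round(quantile * len(row))))
    g_br = float(row[:k].mean())
    if g_br - g_ph < min_contrast:
        raise DegenerateContrastError(
            f"degenerate contrast: g_br - g_ph = {g_br - g_ph:.1f} < {min_contrast}"
        )
    return ThresholdPair.from_grays(g_ph, g_br)


def quantify_area(
    mosaic: np.ndarray,
    well_center: tuple[float, float] | None = None,
    well_radius: float | None = None,
    blur_sigma: float | None = None,
    morph_radius_frac: float = 0.02,
    max_side: int = 2000,
    quantile: float = 0.10,
) -> AreaResult:
    """Relative phase-contrast area of a full-well mosaic.

    Pipeline: downscale (longest side to ``max_side``) -> Gaussian blur
    (``blur_sigma`` px at analysis scale; default 0.8% of the well radius, at
    least 4 px, so smoothing tracks the well size) -> relative thresholds ->
    binarize
    (t_lower <= g <= t_upper) -> erode by a disc of ``morph_radius_frac`` of
    the well radius to sever bridges to peripheral look-alike regions -> keep
    the connected component containing (or nearest to) the image center ->
    dilate by the same element -> restrict to the well circle. The fraction
    is the mask pixel count over the analytic circle area pi * R^2.

    ``well_center``/``well_radius`` (px, at the input scale) default to the
    image center and 48% of the shorter image side (nominal well geometry
    with a small margin).
    """
    img = np.asarray(mosaic, dtype=float)
    h, w = img.shape
    if well_center is None:
        well_center = ((w - 1) / 2.0, (h - 1) / 2.0)
    if well_radius is None:
        well_radius = 0.48 * min(h, w)
    if (
        well_center[0] - well_radius < -0.5
        or well_center[0] + well_radius > w - 0.5
        or well_center[1] - well_radius < -0.5
        or well_center[1] + well_radius > h - 0.5
    ):
        raise ValueError("well circle must lie within the image")

    scale = 1.0
    if max(h, w) > max_side:
        scale = max_side / max(h, w)
        img = transform.resize(
            img / 255.0, (int(h * scale), int(w * scale)), anti_aliasing=True
        ) * 255.0
    center = (well_center[0] * scale, well_center[1] * scale)
    radius = well_radius * scale

    if blur_sigma is None:
        blur_sigma = max(4.0, 0.008 * radius)
    blurred = ndimage.gaussian_filter(img, blur_sigma)
    thr = compute_thresholds(blurred, quantile=quantile)

    binary = (blurred >= thr.t_lower) & (blurred <= thr.t_upper)

    r_elem = max(1, int(round(morph_radius_frac * radius)))
    selem = morphology.disk(r_elem)
    eroded = morphology.erosion(binary, selem)

    central = _central_component(eroded, center)
    if central is None:
        warnings.warn("empty central component; phase-contrast fraction is 0")
        mask = np.zeros_like(binary)
    else:
        mask = morphology.dilation(central, selem)

    hh, ww = mask.shape
    yy, xx = np.mgrid[0:hh, 0:ww]
    inside = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2
    mask &= inside

    fraction = float(np.count_nonzero(mask)) / (np.pi * radius**2)
    return AreaResult(
        mask=mask, fraction=fraction, thresholds=thr, well_radius_px=radius
    )


def _central_component(
    binary: np.ndarray, center: tuple[float, float]
) -> np.ndarray | None:
    """Connected component containing the center pixel, else the component
    whose nearest pixel is closest to the center. None when no foreground."""
    labels, n = ndimage.label(binary)
    if n == 0:
        return None
    cx, cy = int(round(center[0])), int(round(center[1]))
    cy = min(max(cy, 0), binary.shape[0] - 1)
    cx = min(max(cx, 0), binary.shape[1] - 1)
    lab = labels[cy, cx]
    if lab == 0:
        # distance from background-at-center to each component
        yy, xx = np.nonzero(binary)
        d2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2
        lab = labels[yy[np.argmin(d2)], xx[np.argmin(d2)]]
    return labels == lab


def summarize_wells(
    results: list[tuple[float | AreaResult, float | AreaResult]],
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Per-well table of conventional vs adaptive phase-contrast fractions.

    ``results`` holds (conventional, adaptive) pairs as fractions in [0, 1]
    or :class:`AreaResult` objects. Returns per-well fractions and ratios
    plus a summary row with means and sample standard deviations. A zero
    conventional fraction yields a NaN ratio (undefined, not an error).
    """
    if not results:
        raise ValueError("need at least one well")

    def _frac(x: float | AreaResult) -> float:
        return x.fraction if isinstance(x, AreaResult) else float(x)

    conv = np.array([_frac(c) for c, _ in results])
    adap = np.array([_frac(a) for _, a in results])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(conv > 0, adap / conv, np.nan)
    if labels is None:
        labels = [f"well_{i + 1}" for i in range(len(results))]
    df = pd.DataFrame(
        {
            "well": labels,
            "conventional_fraction": conv,
            "adaptive_fraction": adap,
            "ratio": ratio,
        }
    )
    ddof = 1 if len(results) > 1 else 0
    summary = pd.DataFrame(
        {
            "well": ["mean", "std"],
            "conventional_fraction": [conv.mean(), conv.std(ddof=ddof)],
            "adaptive_fraction": [adap.mean(), adap.std(ddof=ddof)],
            "ratio": [np.nanmean(ratio), np.nanstd(ratio, ddof=ddof)],
        }
    )
    return pd.concat([df, summary], ignore_index=True)
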