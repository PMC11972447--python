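"""Image metrics characterizing phase-contrast conditions.

Sharpness (Tenengrad) and mean background gray move in opposite directions as
the condenser annulus slides off the phase ring: contrast is highest and the
background darkest under full overlap. Their strong negative correlation over
a displacement sweep justifies using background brightness alone as the
phase-contrast indicator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats


@dataclass(frozen=True)
class SweepRecord:
    """One step of an annulus-displacement sweep."""

    displacement: float  # px, annulus center deviation (>= 0)
    sharpness: float
    mean_gray: float

    def __post_init__(self) -> None:
        if self.displacement < 0:
            raise ValueError("displacement must be non-negative")


def tenengrad(image: np.ndarray) -> float:
    """Tenengrad sharpness: mean squared Sobel gradient magnitude.

    Horizontal and vertical 3x3 Sobel responses are squared, summed and
    normalized by the pixel count so images of different sizes are
    comparable. Constant images score 0.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("image must be 2-D and at least 3x3")
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    gy = ndimage.sobel(img, axis=0, mode="reflect")
    return float(np.mean(gx**2 + gy**2))


def mean_gray(image: np.ndarray, background_only: bool = False) -> float:
    """Arithmetic mean gray value over the whole image.

    ``background_only`` is reserved for future masking of specimen pixels;
    the whole-image mean is the metric used throughout.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    return float(img.mean())


def sweep_correlation(records: list[SweepRecord]) -> float:
    """Pearson correlation between sharpness and mean gray over a sweep."""
    if len(records) < 3:
        raise ValueError("need at least 3 sweep records")
    s = np.array([r.sharpness for r in records])
    g = np.array([r.mean_gray for r in records])
    if np.ptp(s) == 0 or np.ptp(g) == 0:
        raise ValueError("undefined correlation: a series has zero variance")
    return float(stats.pearsonr(s, g).statistic)


def normalize_sweep(records: list[SweepRecord]) -> list[SweepRecord]:
    """Normalize a sweep to its zero-displacement record, which then reads
    exactly 1.0 in both metrics."""
    ref = min(records, key=lambda r: r.displacement)
    if ref.displacement != 0:
        raise ValueError("sweep has no zero-displacement reference")
    if ref.sharpness == 0 or ref.mean_gray == 0:
        raise ValueError("zero reference value; cannot normalize")
    return [
        SweepRecord(
            displacement=r.displacement,
            sharpness=r.sharpness / ref.sharpness,
            mean_gray=r.mean_gray / ref.mean_gray,
        )
        for r in records
    ]


def measure_sweep(
    sweep: list[tuple[float, np.ndarray, np.ndarray]],
    px_per_mm: float = 1.0,
) -> list[SweepRecord]:
    """Measure sharpness and mean gray on (shift, specimen, bertrand) triples
    as produced by :func:`apc.synthetic.simulate_displacement_sweep`;
    ``px_per_mm`` converts the LCD shift to the displacement seen through the
    secondary camera."""
    return [
        SweepRecord(
            displacement=abs(shift) * px_per_mm,
            sharpness=tenengrad(spec),
            mean_gray=mean_gray(spec),
        )
        for shift, spec, _ in sweep
    ]
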