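"""Acquisition planning: tile grids over a well, autofocus interpolation and
known-coordinate mosaic assembly.

The microscope's field of view is far smaller than a well, so the well disc
is covered by a rectangular grid of overlapping tiles. Focus is anchored at
four well positions and interpolated linearly (a least-squares plane), and
the captured tiles are assembled back into one mosaic at their known grid
coordinates with shading correction, overlap-mean histogram matching and
linear feathering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class TilePlan:
    """Grid of tile centers covering a well disc."""

    centers: list[tuple[float, float]]  # tile centers, same units as fov
    fov: tuple[float, float]  # tile extent (x, y)
    overlap: float
    well_center: tuple[float, float]
    well_radius: float


@dataclass(frozen=True)
class FocusMap:
    """Focus anchors: (position (x, y), z) tuples; interpolation is a
    least-squares plane, exact whenever the anchors are coplanar."""

    anchors: list[tuple[tuple[float, float], float]]
    mode: str = "linear"


def plan_tiles(
    well_center: tuple[float, float],
    well_radius: float,
    fov: tuple[float, float],
    overlap: float = 0.0,
) -> TilePlan:
    """Plan a rectangular tile grid covering the well disc.

    Grid pitch is ``fov - overlap`` per axis; tiles whose rectangle does not
    intersect the well disc are pruned. With ``overlap < min(fov)`` the kept
    tiles cover the disc entirely (any disc point lies inside the tile of its
    grid cell, and that tile intersects the disc).
    """
    if not 0 <= overlap < min(fov):
        raise ValueError("require 0 <= overlap < min(fov)")
    pitch = (fov[0] - overlap, fov[1] - overlap)
    # smallest centered grid whose union spans the well diameter per axis:
    # (n - 1) * pitch + fov >= 2 * well_radius
    nx = max(1, int(np.ceil((2 * well_radius - fov[0]) / pitch[0])) + 1)
    ny = max(1, int(np.ceil((2 * well_radius - fov[1]) / pitch[1])) + 1)
    xs = well_center[0] + (np.arange(nx) - (nx - 1) / 2.0) * pitch[0]
    ys = well_center[1] + (np.arange(ny) - (ny - 1) / 2.0) * pitch[1]
    centers = []
    for y in ys:
        for x in xs:
            if _rect_intersects_circle(
                (x, y), fov, well_center, well_radius
            ):
                centers.append((float(x), float(y)))
    return TilePlan(
        centers=centers,
        fov=fov,
        overlap=overlap,
        well_center=well_center,
        well_radius=well_radius,
    )


def _rect_intersects_circle(
    center: tuple[float, float],
    fov: tuple[float, float],
    ccenter: tuple[float, float],
    radius: float,
) -> bool:
    dx = max(abs(ccenter[0] - center[0]) - fov[0] / 2.0, 0.0)
    dy = max(abs(ccenter[1] - center[1]) - fov[1] / 2.0, 0.0)
    return dx * dx + dy * dy <= radius * radius


def default_focus_anchors(
    well_center: tuple[float, float], well_radius: float
) -> list[tuple[float, float]]:
    """Four equally spaced anchor positions at half-radius on the +-x/+-y
    axes."""
    r = well_radius / 2.0
    cx, cy = well_center
    return [(cx + r, cy), (cx - r, cy), (cx, cy + r), (cx, cy - r)]


def interpolate_focus(fmap: FocusMap, position: tuple[float, float]) -> float:
    """Focal z at ``position`` from the least-squares plane through the
    anchors; extrapolates beyond the anchor hull."""
    if len(fmap.anchors) < 3:
        raise ValueError("degenerate focus anchors: need at least 3")
    xy = np.asarray([a[0] for a in fmap.anchors], dtype=float)
    z = np.asarray([a[1] for a in fmap.anchors], dtype=float)
    a = np.column_stack([xy, np.ones(len(xy))])
    if np.linalg.matrix_rank(a) < 3:
        raise ValueError("degenerate focus anchors: positions are collinear")
    coef, *_ = np.linalg.lstsq(a, z, rcond=None)
    return float(coef[0] * position[0] + coef[1] * position[1] + coef[2])


def assemble_mosaic(
    tiles: list[tuple[np.ndarray, tuple[float, float]]],
    plan: TilePlan,
    shading_ref: np.ndarray | None = None,
    px_per_unit: float = 1.0,
    fill_gray: int = 220,
    match_histograms: bool = True,
) -> np.ndarray:
    """Assemble tiles into a mosaic at their known grid coordinates.

    Each tile is optionally divided by the normalized (blurred) shading
    reference, shifted additively so its mean in the already-covered overlap
    region matches the mosaic, and blended in with linear feathering weights
    that fall off toward the tile border. Planned positions with no tile are
    filled with ``fill_gray`` and flagged with a warning.

    ``px_per_unit`` converts plan coordinates to mosaic pixels.
    """
    if not tiles:
        raise ValueError("no tiles")
    th, tw = tiles[0][0].shape
    for img, _ in tiles:
        if img.shape != (th, tw):
            raise ValueError("all tiles must have the same shape")

    shade = None
    if shading_ref is not None:
        ref = ndimage.gaussian_filter(np.asarray(shading_ref, dtype=float), 5.0)
        shade = ref / ref.mean()

    xs = [c[0] for c in plan.centers]
    ys = [c[1] for c in plan.centers]
    x0 = (min(xs) - plan.fov[0] / 2.0) * px_per_unit
    y0 = (min(ys) - plan.fov[1] / 2.0) * px_per_unit
    wpx = int(np.ceil((max(xs) + plan.fov[0] / 2.0) * px_per_unit - x0))
    hpx = int(np.ceil((max(ys) + plan.fov[1] / 2.0) * px_per_unit - y0))

    acc = np.zeros((hpx, wpx))
    wacc = np.zeros((hpx, wpx))

    # linear feather: weight falls from 1 at the tile center region to ~0 at
    # the border, over the overlap width
    feather_px = max(1, int(round(plan.overlap * px_per_unit / 2.0)))
    fy = np.minimum(np.arange(th) + 1, np.arange(th)[::-1] + 1)
    fx = np.minimum(np.arange(tw) + 1, np.arange(tw)[::-1] + 1)
    weight = (
        np.clip(fy[:, None] / feather_px, 0, 1)
        * np.clip(fx[None, :] / feather_px, 0, 1)
    )

    placed_centers = {(round(c[0], 9), round(c[1], 9)) for _, c in tiles}
    missing = [
        c for c in plan.centers if (round(c[0], 9), round(c[1], 9)) not in placed_centers
    ]
    if missing:
        warnings.warn(f"{len(missing)} planned tiles missing; filled with gray")

    for img, center in tiles:
        tile = np.asarray(img, dtype=float)
        if shade is not None:
            tile = tile / shade
        cx = (center[0] * px_per_unit) - x0
        cy = (center[1] * px_per_unit) - y0
        xa = int(round(cx - tw / 2.0))
        ya = int(round(cy - th / 2.0))
        xa = min(max(xa, 0), wpx - tw)
        ya = min(max(ya, 0), hpx - th)
        sl = np.s_[ya : ya + th, xa : xa + tw]
        if match_histograms:
            covered = wacc[sl] > 0
            if covered.any():
                tile = tile + (
                    (acc[sl][covered] / wacc[sl][covered]).mean()
                    - tile[covered].mean()
                )
        acc[sl] += tile * weight
        wacc[sl] += weight

    out = np.full((hpx, wpx), float(fill_gray))
    nz = wacc > 0
    out[nz] = acc[nz] / wacc[nz]
    return np.clip(np.round(out), 0, 255).astype(np.uint8)
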