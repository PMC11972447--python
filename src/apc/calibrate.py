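"""Linear calibration between observed ring offsets and LCD annulus positions.

The optical train between the LCD (acting as condenser annulus) and the phase
ring is linear, so the LCD position ``p`` (mm) that re-centers the annulus for
an observed Bertrand-image displacement ``delta_d`` (px) follows

    p = k * delta_d + p0

with a single scalar ``k`` (mm/px, identical in x and y) and the default
position ``p0`` at which annulus and phase ring align with no meniscus.
This module fits the model from calibration pairs, maps offsets to corrective
LCD positions, and rasterizes the annulus frame for the LCD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .detect import RingOffset


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted scaling factor and default LCD position of the linear map."""

    k: float  # mm per px
    p0: tuple[float, float]  # mm

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("scaling factor k must be positive")

    def predict(self, delta_d: tuple[float, float]) -> tuple[float, float]:
        return (
            self.k * delta_d[0] + self.p0[0],
            self.k * delta_d[1] + self.p0[1],
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"k_mm_per_px": self.k, "p0_mm": list(self.p0)})
        )

    @staticmethod
    def from_json(path: str | Path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        return CalibrationModel(k=d["k_mm_per_px"], p0=tuple(d["p0_mm"]))


@dataclass(frozen=True)
class FitDiagnostics:
    residuals: np.ndarray
    r_squared: float


def fit_calibration(
    pairs: list[tuple[tuple[float, float], tuple[float, float]]],
) -> tuple[CalibrationModel, FitDiagnostics]:
    """Least-squares fit of the linear offset-to-position calibration.

    ``pairs`` are (offset px (dx, dy), LCD position mm (px_mm, py_mm)). The
    slope k is shared between the axes. When a pair with exactly zero offset
    is present its position is taken as ``p0`` and k is fitted through it on
    the pooled axis data; otherwise k and per-axis intercepts are estimated
    jointly by least squares and ``p0`` is the intercept pair.
    """
    if len(pairs) < 2:
        raise CalibrationError("underdetermined: need at least 2 calibration pairs")
    d = np.asarray([p[0] for p in pairs], dtype=float)
    p = np.asarray([p[1] for p in pairs], dtype=float)
    if len(np.unique(d, axis=0)) < 2:
        raise CalibrationError("underdetermined: offsets are not distinct")

    zero_rows = np.where(np.all(d == 0.0, axis=1))[0]
    if len(zero_rows) > 0:
        p0 = p[zero_rows[0]]
        dp = p - p0
        x = d.ravel()
        y = dp.ravel()
        denom = float(x @ x)
        if denom == 0.0:
            raise CalibrationError("underdetermined: all offsets zero")
        k = float(x @ y) / denom
        pred = k * d + p0
    else:
        # design: [dx, 1, 0; dy, 0, 1] per pair -> unknowns (k, p0x, p0y)
        n = len(pairs)
        a = np.zeros((2 * n, 3))
        a[0::2, 0] = d[:, 0]
        a[1::2, 0] = d[:, 1]
        a[0::2, 1] = 1.0
        a[1::2, 2] = 1.0
        y = p.ravel()
        sol, *_ = np.linalg.lstsq(a, y, rcond=None)
        k, p0 = float(sol[0]), np.array([sol[1], sol[2]])
        pred = k * d + p0

    if k <= 0:
        raise CalibrationError("inconsistent calibration: fitted k is not positive")
    resid = (p - pred).ravel()
    tot = np.sum((p.ravel() - p.ravel().mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2)) / tot if tot > 0 else 1.0
    return (
        CalibrationModel(k=k, p0=(float(p0[0]), float(p0[1]))),
        FitDiagnostics(residuals=resid, r_squared=r2),
    )


def map_offset_to_lcd(
    offset: RingOffset | tuple[float, float],
    model: CalibrationModel,
    full_resolution: bool = False,
) -> tuple[float, float]:
    """Corrective LCD position (mm) for an observed ring offset.

    A :class:`RingOffset` carries its analysis scale; set ``full_resolution``
    when the model was calibrated against full-resolution pixel offsets so
    the offset is rescaled before applying the linear map. A bare (dx, dy)
    tuple is used as-is.
    """
    if isinstance(offset, RingOffset):
        dd = offset.delta_d_full_resolution if full_resolution else offset.delta_d
    else:
        dd = tuple(offset)
    if not np.all(np.isfinite(dd)):
        raise ValueError("offset must be finite")
    return model.predict((float(dd[0]), float(dd[1])))


# --------------------------------------------------------------------------- #
# LCD annulus rasterization
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class AnnulusSpec:
    """Geometry of the virtual annulus on the LCD raster.

    ``center`` is in LCD millimetre coordinates with the origin at the raster
    top-left pixel center; ``pixel_pitch`` converts raster pixels to mm.
    """

    center: tuple[float, float]  # mm
    r_inner: float  # mm
    r_outer: float  # mm
    lcd_resolution: tuple[int, int]  # (width, height) px
    pixel_pitch: float  # mm per px

    def __post_init__(self) -> None:
        if not 0 < self.r_inner < self.r_outer:
            raise ValueError("require 0 < r_inner < r_outer")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")


def render_annulus_frame(spec: AnnulusSpec, white_screen: bool = False) -> np.ndarray:
    """Binary LCD raster: white (transmissive, 255) inside the annulus band,
    black elsewhere. ``white_screen`` returns an all-white frame (brightfield
    conditions for the phase-ring calibration image)."""
    w, h = spec.lcd_resolution
    if white_screen:
        return np.full((h, w), 255, dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    r_mm = np.hypot(
        xx * spec.pixel_pitch - spec.center[0],
        yy * spec.pixel_pitch - spec.center[1],
    )
    band = (r_mm >= spec.r_inner) & (r_mm <= spec.r_outer)
    if not band.any():
        raise CalibrationError("clipped annulus: ring lies fully outside the raster")
    return np.where(band, 255, 0).astype(np.uint8)
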