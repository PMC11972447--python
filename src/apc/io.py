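"""Reading and writing of images, ground-truth sidecars and calibration CSVs."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synthetic import BertrandGroundTruth, WellGroundTruth

PAIRS_COLUMNS = ["dx_px", "dy_px", "px_mm", "py_mm"]


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale image (PNG/TIFF); color inputs are averaged."""
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def write_bertrand_truth(path: str | Path, truth: BertrandGroundTruth) -> None:
    Path(path).write_text(json.dumps(asdict(truth)))


def write_well_truth(path: str | Path, truth: WellGroundTruth) -> None:
    d = asdict(truth)
    d.pop("phase_mask")
    Path(path).write_text(json.dumps(d))


def write_pairs_csv(
    path: str | Path,
    pairs: list[tuple[tuple[float, float], tuple[float, float]]],
) -> None:
    rows = [(d[0], d[1], p[0], p[1]) for d, p in pairs]
    pd.DataFrame(rows, columns=PAIRS_COLUMNS).to_csv(path, index=False)


def read_pairs_csv(
    path: str | Path,
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    df = pd.read_csv(path)
    missing = set(PAIRS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"calibration CSV missing columns: {sorted(missing)}")
    return [
        ((r.dx_px, r.dy_px), (r.px_mm, r.py_mm)) for r in df.itertuples(index=False)
    ]
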