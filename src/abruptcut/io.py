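"""File I/O: PNG images and masks, JSON contours, overlay rasters."""
from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "read_image",
    "read_mask",
    "write_mask",
    "save_polylines",
    "load_polylines",
    "overlay_borders",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read an RGB image; alpha and grayscale inputs are normalized to 3 channels."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr.astype(np.uint8)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel PNG mask, binarized at > 127."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return (arr > 127).astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


def save_polylines(path: str | Path, polylines: list[np.ndarray]) -> None:
    payload = [np.asarray(p, dtype=float).tolist() for p in polylines]
    Path(path).write_text(json.dumps(payload))


def load_polylines(path: str | Path) -> list[np.ndarray]:
    return [np.asarray(p, dtype=float) for p in json.loads(Path(path).read_text())]


def _paint(canvas: np.ndarray, polyline: np.ndarray, color: tuple[int, int, int]) -> None:
    h, w = canvas.shape[:2]
    pts = np.round(np.asarray(polyline, dtype=float)).astype(int)
    ok = (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
    canvas[pts[ok, 0], pts[ok, 1]] = color


def overlay_borders(
    image: np.ndarray,
    original: np.ndarray | None = None,
    contracted: list[np.ndarray] | None = None,
    path: str | Path | None = None,
) -> np.ndarray:
    """Visual audit raster: original border in green, contracted in red."""
    canvas = np.asarray(image).astype(np.uint8).copy()
    if original is not None:
        _paint(canvas, original, (0, 255, 0))
    for loop in contracted or []:
        _paint(canvas, loop, (255, 0, 0))
    if path is not None:
        iio.imwrite(path, canvas)
    return canvas
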