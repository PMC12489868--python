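"""Reading and writing images and frame directories.

Decoding is delegated to imageio; 8- and 16-bit integer images are scaled to
[0, 1] on the way in and written back at their source depth.
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .imaging import FrameSequence, GrayImage, rgb_to_value

__all__ = ["read_image", "read_frames", "write_image"]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


def _to_unit(arr: np.ndarray) -> tuple[np.ndarray, int]:
    """Scale an integer or float image array to [0, 1]; return (array, depth)."""
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0, 8
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0, 16
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(arr.astype(np.float64), 0.0, 1.0), 8
    raise ValueError(f"unsupported image dtype {arr.dtype}")


def read_image(path: str | os.PathLike) -> GrayImage:
    """Read a PNG/TIFF/JPEG as a luminance image.

    RGB(A) inputs are converted through the HSV value channel; grayscale
    inputs are scaled to [0, 1].
    """
    raw = np.asarray(iio.imread(path))
    if raw.ndim == 3:
        if raw.shape[2] == 4:  # drop alpha
            raw = raw[:, :, :3]
        arr, depth = _to_unit(raw)
        return rgb_to_value(arr, source_depth=depth)
    arr, depth = _to_unit(raw)
    return GrayImage(arr, source_depth=depth)


def read_frames(path: str | os.PathLike, frame_rate: float = 50.0) -> FrameSequence:
    """Read a directory of frame images, sorted lexicographically by name."""
    directory = Path(path)
    if not directory.is_dir():
        raise ValueError(f"{directory} is not a directory of frames")
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
    )
    if not files:
        raise ValueError(f"no frame images found under {directory}")
    return FrameSequence(
        frames=tuple(read_image(p) for p in files), frame_rate=frame_rate
    )


def write_image(path: str | os.PathLike, img: GrayImage) -> None:
    """Write a luminance image as PNG/TIFF at its source bit depth."""
    if img.source_depth == 16:
        out = np.round(img.pixels * 65535.0).astype(np.uint16)
    else:
        out = np.round(img.pixels * 255.0).astype(np.uint8)
    iio.imwrite(path, out)
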