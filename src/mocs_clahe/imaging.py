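"""Luminance images, focus measurement and exposure classification.

The pipeline operates on the HSV value channel of slit-lamp conjunctival
frames: a bright scleral background crossed by dark microvessels.  All
computation happens on floating-point luminance in [0, 1]; the original bit
depth is carried along only so outputs can be written back at source scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage

__all__ = [
    "ExposureClass",
    "GrayImage",
    "FrameSequence",
    "rgb_to_value",
    "mean_luminosity",
    "classify_exposure",
    "sharpness_log_variance",
    "select_sharpest_frame",
]

#: Mean-luminosity thresholds separating under/correct/over exposure.
#: Conjunctival images have negatively skewed histograms dominated by the
#: bright sclera, so a "correct" exposure sits well above mid-gray.
UNDEREXPOSED_MAX = 0.6
CORRECT_MAX = 0.8


class ExposureClass(str, Enum):
    """Exposure category of a frame, decided from its mean luminosity."""

    UNDEREXPOSED = "underexposed"
    CORRECT = "correct"
    OVEREXPOSED = "overexposed"


@dataclass(frozen=True)
class GrayImage:
    """A 2-D luminance image with values in [0, 1].

    Parameters
    ----------
    pixels : ndarray of float, shape (H, W)
        Luminance values in [0, 1].  At least 3x3, which the interior-pixel
        noise estimator requires.
    source_depth : int
        Bit depth of the source data (8 or 16); used only at I/O time.
    """

    pixels: np.ndarray
    source_depth: int = 8

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2-D luminance array, got ndim={arr.ndim}")
        if arr.shape[0] < 3 or arr.shape[1] < 3:
            raise ValueError(f"image must be at least 3x3, got {arr.shape}")
        lo, hi = float(arr.min()), float(arr.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"pixel values must lie in [0, 1], got range [{lo}, {hi}]")
        arr = np.clip(arr, 0.0, 1.0)
        arr.setflags(write=False)
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class FrameSequence:
    """An ordered burst of same-sized frames (a short video clip)."""

    frames: tuple[GrayImage, ...]
    frame_rate: float = 50.0

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if not frames:
            raise ValueError("frame sequence must be non-empty")
        shape = frames[0].shape
        for k, f in enumerate(frames):
            if f.shape != shape:
                raise ValueError(
                    f"frame {k} has shape {f.shape}, expected {shape}"
                )
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> GrayImage:
        return self.frames[i]


def rgb_to_value(rgb: np.ndarray, source_depth: int = 8) -> GrayImage:
    """Extract the HSV value channel V = max(R, G, B) from an RGB image.

    Chromatic information is discarded; only luminosity is kept for
    enhancement.  Input values must already be scaled to [0, 1].
    """
    arr = np.asarray(rgb, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {arr.shape}")
    return GrayImage(arr.max(axis=2), source_depth=source_depth)


def mean_luminosity(img: GrayImage) -> float:
    """Average luminosity V_avg: the arithmetic mean over all pixels."""
    return float(img.pixels.mean())


def classify_exposure(v_avg: float) -> ExposureClass:
    """Classify a mean luminosity into under/correct/over exposure.

    V_avg <= 0.6 is underexposed, 0.6 < V_avg <= 0.8 correct-exposed and
    V_avg > 0.8 overexposed; both boundaries belong to the lower class.
    """
    if not 0.0 <= v_avg <= 1.0:
        raise ValueError(f"v_avg must lie in [0, 1], got {v_avg}")
    if v_avg <= UNDEREXPOSED_MAX:
        return ExposureClass.UNDEREXPOSED
    if v_avg <= CORRECT_MAX:
        return ExposureClass.CORRECT
    return ExposureClass.OVEREXPOSED


def sharpness_log_variance(img: GrayImage, log_sigma: float = 2.0) -> float:
    """Focus measure: variance of the Laplacian-of-Gaussian response.

    Defocused frames have weak high-frequency content, so the LoG response
    flattens and its variance drops; the sharper the frame the larger the
    score.  Reflect padding avoids spurious edge response.
    """
    if log_sigma <= 0:
        raise ValueError(f"log_sigma must be positive, got {log_sigma}")
    # truncate=3 gives a kernel half-width of ceil(3*sigma)
    response = ndimage.gaussian_laplace(
        img.pixels, sigma=log_sigma, mode="reflect", truncate=3.0
    )
    return float(response.var())


def select_sharpest_frame(seq: FrameSequence, log_sigma: float = 2.0) -> int:
    """Index of the most focused frame; ties go to the lowest index."""
    scores = [sharpness_log_variance(f, log_sigma) for f in seq.frames]
    return int(np.argmax(scores))
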