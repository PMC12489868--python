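"""The two search objectives: texture contrast up, noise amplification down.

Contrast is the Haralick contrast of the gray-level co-occurrence matrix
(GLCM), sum_ij (i-j)^2 p_ij, which grows with local intensity variation.
Noise is estimated with the fast noise-variance estimator: the image is
convolved with the difference of two 3x3 Laplacian approximations

    N = [[ 1, -2,  1],
         [-2,  4, -2],
         [ 1, -2,  1]]

whose response to i.i.d. noise of standard deviation sigma has variance
36 sigma^2 while annihilating constant and linear image structure; the
scaled mean absolute response over interior pixels,

    sigma_n = sqrt(pi/2) * (1 / (6 (W-2)(H-2))) * sum |I * N|,

is a consistent estimate of sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve2d

from .clahe import ClaheParams, clahe
from .imaging import GrayImage

__all__ = [
    "GlcmConfig",
    "FitnessPair",
    "glcm",
    "glcm_contrast",
    "fnve",
    "evaluate_candidate",
    "FNVE_KERNEL",
]

#: Difference of two 3x3 Laplacian approximations; squared coefficients sum to 36.
FNVE_KERNEL = np.array(
    [[1.0, -2.0, 1.0], [-2.0, 4.0, -2.0], [1.0, -2.0, 1.0]]
)


@dataclass(frozen=True)
class GlcmConfig:
    """Quantization and offset used to accumulate the co-occurrence matrix.

    ``levels`` gray levels by uniform binning of [0, 1]; a single ``offset``
    (row, col) displacement, symmetric accumulation by default — the most
    widespread defaults for Haralick features.
    """

    levels: int = 8
    offset: tuple[int, int] = (0, 1)
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        if tuple(self.offset) == (0, 0):
            raise ValueError("offset must be non-zero")


@dataclass(frozen=True)
class FitnessPair:
    """Objective values of a candidate: contrast to maximize, noise to minimize."""

    contrast: float
    noise: float

    @property
    def minimized(self) -> tuple[float, float]:
        """Both objectives under the minimization convention: (-contrast, noise)."""
        return (-self.contrast, self.noise)

    @property
    def is_finite(self) -> bool:
        return math.isfinite(self.contrast) and math.isfinite(self.noise)


def glcm(img: GrayImage, cfg: GlcmConfig = GlcmConfig()) -> np.ndarray:
    """Normalized gray-level co-occurrence matrix at the configured offset.

    Entries are joint frequencies of quantized gray-level pairs at the
    (row, col) displacement; with symmetric accumulation each ordered pair
    is counted in both directions.  The result sums to 1.
    """
    dr, dc = cfg.offset
    H, W = img.shape
    if H <= abs(dr) or W <= abs(dc):
        raise ValueError(
            f"image of shape {img.shape} has no pixel pairs at offset {cfg.offset}"
        )
    L = cfg.levels
    q = np.minimum((img.pixels * L).astype(np.intp), L - 1)

    r0, r1 = max(0, -dr), H - max(0, dr)
    c0, c1 = max(0, -dc), W - max(0, dc)
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]

    P = np.zeros((L, L))
    np.add.at(P, (a.ravel(), b.ravel()), 1.0)
    if cfg.symmetric:
        P = P + P.T
    return P / P.sum()


def glcm_contrast(P: np.ndarray) -> float:
    """Haralick contrast sum_ij (i - j)^2 p_ij of a normalized GLCM."""
    P = np.asarray(P, dtype=np.float64)
    if abs(P.sum() - 1.0) > 1e-6:
        raise ValueError(f"GLCM must be normalized; sums to {P.sum()}")
    i, j = np.indices(P.shape)
    return float(((i - j) ** 2 * P).sum())


def fnve(img: GrayImage) -> float:
    """Fast noise-variance estimate: sigma_n of additive noise on [0, 1] scale.

    Exact zero for constant and linear-ramp images (the kernel is a double
    second difference).  Values comparable to 8-bit-scale figures require
    multiplying by 255.
    """
    H, W = img.shape
    response = convolve2d(img.pixels, FNVE_KERNEL, mode="valid")
    return float(
        math.sqrt(math.pi / 2.0)
        * np.abs(response).sum()
        / (6.0 * (W - 2) * (H - 2))
    )


def evaluate_candidate(
    img: GrayImage, params: ClaheParams, cfg: GlcmConfig = GlcmConfig()
) -> FitnessPair:
    """Enhance with the candidate parameters and score the result."""
    enhanced = clahe(img, params)
    return FitnessPair(
        contrast=glcm_contrast(glcm(enhanced, cfg)), noise=fnve(enhanced)
    )
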