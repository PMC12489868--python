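"""Full-reference quality metrics: MSE, PSNR and a global SSIM.

Metrics operate on the 8-bit-scaled representation of the internal [0, 1]
images — PSNR uses the peak (L-1)^2 and SSIM the stabilizing constants
C1 = (K1 L)^2, C2 = (K2 L)^2 with K1 = 0.01 and K2 = 0.03.  SSIM here is a
single global statistic over whole-image means, variances and covariance;
the familiar sliding-window variant is available via ``mode="windowed"``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from skimage.metrics import structural_similarity as _skimage_ssim

from .imaging import GrayImage

__all__ = ["QualityReport", "mse", "psnr", "ssim_global", "ssim", "quality_report"]


@dataclass(frozen=True)
class QualityReport:
    """PSNR/SSIM of an enhanced image against its original.

    ``niqe`` is filled only when a user supplies an external no-reference
    evaluator; it is recorded verbatim.
    """

    psnr: float
    ssim: float
    niqe: float | None = None

    def to_dict(self) -> dict:
        return {"psnr": self.psnr, "ssim": self.ssim, "niqe": self.niqe}


def _check_pair(a: GrayImage, b: GrayImage) -> None:
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")


def mse(original: GrayImage, enhanced: GrayImage, levels: int = 256) -> float:
    """Mean squared error on the (levels-1)-scaled gray-level representation."""
    _check_pair(original, enhanced)
    diff = (original.pixels - enhanced.pixels) * (levels - 1)
    return float(np.mean(diff * diff))


def psnr(original: GrayImage, enhanced: GrayImage, levels: int = 256) -> float:
    """Peak signal-to-noise ratio 10 log10((L-1)^2 / MSE), in decibels.

    Identical images have zero MSE; +infinity is returned with a warning
    rather than raising.
    """
    m = mse(original, enhanced, levels)
    if m == 0:
        warnings.warn("identical images: PSNR is infinite", stacklevel=2)
        return math.inf
    return 10.0 * math.log10((levels - 1) ** 2 / m)


def ssim_global(
    original: GrayImage,
    enhanced: GrayImage,
    levels: int = 256,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Single-window structural similarity over whole-image statistics.

    SSIM = (2 mu_x mu_y + C1)(2 cov + C2) /
           ((mu_x^2 + mu_y^2 + C1)(var_x + var_y + C2)).
    """
    _check_pair(original, enhanced)
    x = original.pixels * (levels - 1)
    y = enhanced.pixels * (levels - 1)
    c1 = (k1 * levels) ** 2
    c2 = (k2 * levels) ** 2
    mu_x, mu_y = x.mean(), y.mean()
    var_x, var_y = x.var(), y.var()
    cov = float(np.mean((x - mu_x) * (y - mu_y)))
    return float(
        (2 * mu_x * mu_y + c1)
        * (2 * cov + c2)
        / ((mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2))
    )


def ssim(
    original: GrayImage,
    enhanced: GrayImage,
    levels: int = 256,
    mode: str = "global",
) -> float:
    """SSIM with selectable flavour: "global" (default) or "windowed"."""
    if mode == "global":
        return ssim_global(original, enhanced, levels)
    if mode == "windowed":
        _check_pair(original, enhanced)
        return float(
            _skimage_ssim(
                original.pixels * (levels - 1),
                enhanced.pixels * (levels - 1),
                data_range=levels - 1,
            )
        )
    raise ValueError(f"unknown ssim mode {mode!r}")


def quality_report(
    original: GrayImage,
    enhanced: GrayImage,
    levels: int = 256,
    niqe_fn: Callable[[GrayImage], float] | None = None,
) -> QualityReport:
    """Assemble PSNR/global-SSIM (and optionally external NIQE) in one report."""
    return QualityReport(
        psnr=psnr(original, enhanced, levels),
        ssim=ssim_global(original, enhanced, levels),
        niqe=None if niqe_fn is None else float(niqe_fn(enhanced)),
    )
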