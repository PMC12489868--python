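"""Synthetic conjunctiva-like phantoms with known ground truth.

A phantom emulates the salient features of a slit-lamp conjunctival frame:
dark curvilinear vessels on a bright, radially vignetted scleral background,
a negatively skewed intensity histogram, additive Gaussian sensor noise, and
optional defocus blur.  Vessels are drawn as seeded random walks with
momentum and a Gaussian transverse profile — curvilinear dark structures
with tunable contrast, no anatomical model.

Because the ground truth (vessel mask, noise sigma, exposure class, blur)
is known, every pipeline stage can be tested without any acquired data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .imaging import ExposureClass, FrameSequence, GrayImage, classify_exposure, mean_luminosity

__all__ = ["PhantomSpec", "PhantomBundle", "generate_phantom", "generate_sequence", "exposure_suite"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic conjunctival frame.

    Defaults describe a correctly exposed frame from a consumer CMOS sensor
    at moderate ISO: bright background (mean luminosity ~0.7 after the
    vignette), vessels ~3 px wide darker than the sclera by 0.25, mild
    radial vignette, sensor noise sigma 0.01 on the [0, 1] scale, in focus.
    """

    width: int = 128
    height: int = 128
    n_vessels: int = 6
    vessel_width: float = 3.0
    vessel_contrast: float = 0.25
    background_level: float = 0.75
    vignette_strength: float = 0.15
    noise_sigma: float = 0.01
    blur_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 3 or self.height < 3:
            raise ValueError("phantom must be at least 3x3")
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be non-negative")
        if self.vessel_width <= 0:
            raise ValueError("vessel_width must be positive")
        if not 0.0 <= self.vessel_contrast <= 1.0:
            raise ValueError("vessel_contrast must lie in [0, 1]")
        if not 0.0 <= self.background_level <= 1.0:
            raise ValueError("background_level must lie in [0, 1]")
        if self.background_level - self.vessel_contrast < 0:
            raise ValueError("vessel_contrast may not exceed background_level")
        if not 0.0 <= self.vignette_strength < 1.0:
            raise ValueError("vignette_strength must lie in [0, 1)")
        if self.noise_sigma < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sigma and blur_sigma must be non-negative")


@dataclass(frozen=True)
class PhantomBundle:
    """A phantom image together with its ground truth."""

    image: GrayImage
    vessel_mask: np.ndarray
    true_noise_sigma: float
    exposure_target: ExposureClass

    def __post_init__(self) -> None:
        if self.vessel_mask.shape != self.image.shape:
            raise ValueError("vessel mask must match image dimensions")


def _vessel_depth(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Normalized [0, 1] vessel depth map from random walks with momentum."""
    H, W = spec.height, spec.width
    canvas = np.zeros((H, W))
    n_steps = int(1.5 * max(H, W))
    for _ in range(spec.n_vessels):
        y = rng.uniform(0, H)
        x = rng.uniform(0, W)
        theta = rng.uniform(0, 2 * math.pi)
        for _ in range(n_steps):
            theta += rng.normal(0.0, 0.15)  # momentum: small heading changes
            y += math.sin(theta)
            x += math.cos(theta)
            iy, ix = int(round(y)), int(round(x))
            if 0 <= iy < H and 0 <= ix < W:
                canvas[iy, ix] = 1.0
    if canvas.max() == 0:
        return canvas
    depth = ndimage.gaussian_filter(canvas, sigma=spec.vessel_width / 2.0)
    return depth / depth.max()


def _render(spec: PhantomSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless phantom and vessel mask (before blur and noise)."""
    H, W = spec.height, spec.width
    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    r2 = ((yy - cy) / max(cy, 1)) ** 2 + ((xx - cx) / max(cx, 1)) ** 2
    background = spec.background_level * (1.0 - spec.vignette_strength * r2 / 2.0)

    depth = _vessel_depth(spec, rng)
    clean = np.clip(background - spec.vessel_contrast * depth, 0.0, 1.0)
    mask = depth > 0.5
    return clean, mask


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Render a phantom: background + vessels, then blur, then sensor noise.

    Noise is added after defocus blur, mimicking sensor noise on a defocused
    optical image, and the result is clipped to [0, 1]; the recorded ground
    truth sigma refers to the pre-clipping noise (a small bias remains near
    saturation).
    """
    rng = np.random.default_rng(spec.seed)
    clean, mask = _render(spec, rng)
    if spec.blur_sigma > 0:
        clean = ndimage.gaussian_filter(clean, sigma=spec.blur_sigma)
    noisy = clean + rng.normal(0.0, spec.noise_sigma, clean.shape) if spec.noise_sigma > 0 else clean
    img = GrayImage(np.clip(noisy, 0.0, 1.0))
    return PhantomBundle(
        image=img,
        vessel_mask=mask,
        true_noise_sigma=spec.noise_sigma,
        exposure_target=classify_exposure(mean_luminosity(img)),
    )


def generate_sequence(
    spec: PhantomSpec, n_frames: int, blur_schedule: list[float]
) -> FrameSequence:
    """A frame burst of one phantom under a per-frame defocus schedule.

    All frames share the same underlying scene; frame ``argmin(blur)`` is
    the ground-truth sharpest.  Per-frame noise realizations differ but are
    deterministic given the spec seed.
    """
    if len(blur_schedule) != n_frames:
        raise ValueError(
            f"blur schedule has {len(blur_schedule)} entries for {n_frames} frames"
        )
    rng = np.random.default_rng(spec.seed)
    clean, _ = _render(spec, rng)
    frames = []
    for sigma in blur_schedule:
        if sigma < 0:
            raise ValueError("blur sigmas must be non-negative")
        frame = ndimage.gaussian_filter(clean, sigma=sigma) if sigma > 0 else clean
        if spec.noise_sigma > 0:
            frame = frame + rng.normal(0.0, spec.noise_sigma, frame.shape)
        frames.append(GrayImage(np.clip(frame, 0.0, 1.0)))
    return FrameSequence(frames=tuple(frames))


#: Target mean luminosities for the three exposure classes.
_EXPOSURE_TARGETS = {
    ExposureClass.UNDEREXPOSED: 0.45,
    ExposureClass.CORRECT: 0.70,
    ExposureClass.OVEREXPOSED: 0.88,
}


def exposure_suite(
    base_spec: PhantomSpec | None = None,
) -> dict[ExposureClass, PhantomBundle]:
    """Three phantoms, one per exposure class, verified by classification.

    The background level is adjusted by fixed-point iteration until the
    rendered mean luminosity lands at the class target (vessels and the
    vignette pull the mean below the nominal background).
    """
    base_spec = base_spec or PhantomSpec()
    suite: dict[ExposureClass, PhantomBundle] = {}
    for label, target in _EXPOSURE_TARGETS.items():
        bg = target
        bundle = None
        for _ in range(12):
            bg = float(np.clip(bg, base_spec.vessel_contrast, 1.0))
            bundle = generate_phantom(replace(base_spec, background_level=bg))
            m = mean_luminosity(bundle.image)
            if abs(m - target) < 5e-3:
                break
            bg += target - m
        assert bundle is not None
        if bundle.exposure_target != label:
            raise RuntimeError(
                f"could not reach exposure class {label} (mean "
                f"{mean_luminosity(bundle.image):.3f})"
            )
        suite[label] = bundle
    return suite
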