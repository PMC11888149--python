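"""Parametric image degradations for robustness studies.

Six corruption scenarios common in capsule-endoscopy acquisition are
simulated: lens fogging, additive Gaussian sensor noise, defocus blur,
linear motion blur, random brightness (power-law transform), and HSV color
jitter.  Each operator maps a valid 8-bit RGB frame to a valid 8-bit RGB
frame of the same shape; none of them moves pixels, so ground-truth masks
are reused unchanged on corrupted frames.

Default parameter ranges:

========================  =======================================
fog                       intensity in [0.25, 1], disk alpha 0.05
gaussian_noise            zero mean, variance in [5, 300]
defocus                   disk radius in [1, 8] px
motion_blur               angle in {0, 15, ..., 345} deg, length in [1, 25] px
brightness                gamma in [0.75, 1.25], S = r^(1/gamma)
color_jitter              H/S/V shifts each in [-5, 5] 8-bit units
========================  =======================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.ndimage import convolve
from skimage.color import hsv2rgb, rgb2hsv

from .image_io import validate_image

__all__ = [
    "SCENARIOS",
    "DegradationConfig",
    "CorruptedSet",
    "apply_fog",
    "apply_gaussian_noise",
    "apply_defocus",
    "apply_motion_blur",
    "apply_brightness",
    "apply_color_jitter",
    "apply_scenario",
    "corrupt_dataset",
]

SCENARIOS = ("fog", "gaussian_noise", "defocus", "motion_blur", "brightness", "color_jitter")

#: default sampling ranges, overridable per DegradationConfig
DEFAULT_PARAMS: dict[str, dict[str, Any]] = {
    "fog": {"intensity": (0.25, 1.0), "transparency": 0.05},
    # the noise-variance range is configurable; (5, 300) is the primary
    # setting, (5, 50) the documented milder alternative
    "gaussian_noise": {"variance": (5.0, 300.0)},
    "defocus": {"radius": (1.0, 8.0)},
    "motion_blur": {"angle_step_deg": 15, "length": (1, 25)},
    "brightness": {"gamma": (0.75, 1.25)},
    "color_jitter": {"shift": (-5.0, 5.0)},
}


@dataclass(frozen=True)
class DegradationConfig:
    """One corruption scenario plus its sampling ranges and seed."""

    scenario: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        merged = {**DEFAULT_PARAMS[self.scenario], **self.params}
        object.__setattr__(self, "params", merged)


@dataclass(frozen=True)
class CorruptedSet:
    """Corrupted frames with full provenance (source, scenario, params, seed)."""

    images: list[np.ndarray]
    provenance: list[dict[str, Any]]

    def __len__(self) -> int:
        return len(self.images)


def _finalize(float_img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(float_img), 0, 255).astype(np.uint8)


def apply_fog(
    image: np.ndarray,
    intensity: float,
    transparency: float = 0.05,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Composite soft white disks over the frame, emulating lens condensation.

    ``intensity`` in [0.25, 1] scales the expected number of fog disks;
    each disk is alpha-blended with per-disk opacity ``transparency``
    (0.05 by default) and a soft quadratic edge profile.
    """
    if not 0.25 <= intensity <= 1.0:
        raise ValueError(f"fog intensity must be in [0.25, 1], got {intensity}")
    image = validate_image(image)
    rng = np.random.default_rng() if rng is None else rng
    h, w = image.shape[:2]
    out = image.astype(np.float64)
    # disk count scales with intensity and frame area (reference density at 336^2)
    lam = intensity * 150.0 * (h * w) / (336.0 * 336.0)
    n_disks = int(rng.poisson(lam))
    yy, xx = np.mgrid[:h, :w]
    for _ in range(n_disks):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = rng.uniform(0.05, 0.25) * min(h, w)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        alpha = transparency * np.clip(1.0 - d2 / r**2, 0.0, 1.0)
        out = out * (1.0 - alpha[..., None]) + 255.0 * alpha[..., None]
    return _finalize(out)


def apply_gaussian_noise(
    image: np.ndarray,
    variance: float,
    rng: np.random.Generator | None = None,
    check_range: bool = True,
) -> np.ndarray:
    """Add zero-mean Gaussian noise of the given variance per pixel per channel.

    ``check_range`` enforces the study range [5, 300]; disabling it permits
    any variance >= 0 (variance 0 is the identity).
    """
    if check_range and not 5.0 <= variance <= 300.0:
        raise ValueError(f"noise variance must be in [5, 300], got {variance}")
    if variance < 0:
        raise ValueError(f"noise variance must be >= 0, got {variance}")
    image = validate_image(image)
    if variance == 0:
        return image.copy()
    rng = np.random.default_rng() if rng is None else rng
    noisy = image.astype(np.float64) + rng.normal(0.0, np.sqrt(variance), image.shape)
    return _finalize(noisy)


def disk_kernel(radius: float) -> np.ndarray:
    """Normalised disk point-spread function with an anti-aliased (soft) edge."""
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    r_int = int(np.ceil(radius))
    if r_int == 0:
        return np.ones((1, 1))
    yy, xx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    dist = np.sqrt(yy**2 + xx**2)
    kernel = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    return kernel / kernel.sum()


def line_kernel(angle_deg: float, length_px: int) -> np.ndarray:
    """Normalised anti-aliased line kernel for linear motion blur.

    Built by bilinear splatting of points sampled densely along the centred
    segment, so an angle and its opposite (angle + 180) give the same kernel.
    """
    angle = float(angle_deg) % 180.0  # a line has no direction
    if length_px == 1:
        return np.ones((1, 1))
    half = (length_px - 1) / 2.0
    size = 2 * int(np.ceil(half)) + 1
    kernel = np.zeros((size, size))
    c = size // 2
    theta = np.deg2rad(angle)
    t = np.linspace(-half, half, 8 * length_px)
    px = c + t * np.cos(theta)
    py = c - t * np.sin(theta)  # image rows grow downward
    x0, y0 = np.floor(px).astype(int), np.floor(py).astype(int)
    fx, fy = px - x0, py - y0
    for dx, dy, wgt in (
        (0, 0, (1 - fx) * (1 - fy)),
        (1, 0, fx * (1 - fy)),
        (0, 1, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        np.add.at(kernel, (np.clip(y0 + dy, 0, size - 1), np.clip(x0 + dx, 0, size - 1)), wgt)
    return kernel / kernel.sum()


def _convolve_channels(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    out = np.empty(image.shape, dtype=np.float64)
    for ch in range(3):
        out[:, :, ch] = convolve(image[:, :, ch].astype(np.float64), kernel, mode="reflect")
    return out


def apply_defocus(
    image: np.ndarray, radius: float, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Convolve each channel with a normalised disk PSF (out-of-focus lens)."""
    image = validate_image(image)
    kernel = disk_kernel(radius)
    if kernel.size == 1:
        return image.copy()
    return _finalize(_convolve_channels(image, kernel))


def apply_motion_blur(
    image: np.ndarray,
    angle_deg: float,
    length_px: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Convolve with a normalised line kernel (capsule motion during exposure).

    ``angle_deg`` must lie on the 15-degree grid in [0, 360); ``length_px``
    (the motion extent) in [1, 25].
    """
    if not (0 <= angle_deg < 360 and float(angle_deg) % 15 == 0):
        raise ValueError(f"angle must be a multiple of 15 in [0, 360), got {angle_deg}")
    if not 1 <= length_px <= 25:
        raise ValueError(f"length must be in [1, 25] px, got {length_px}")
    image = validate_image(image)
    kernel = line_kernel(angle_deg, int(length_px))
    if kernel.size == 1:
        return image.copy()
    return _finalize(_convolve_channels(image, kernel))


def apply_brightness(image: np.ndarray, gamma: float, check_range: bool = True) -> np.ndarray:
    """Power-law brightness change: S = r^(1/gamma) on normalised intensities.

    With this exponent convention gamma > 1 brightens and gamma < 1 darkens.
    ``check_range`` enforces the study range [0.75, 1.25].
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    if check_range and not 0.75 <= gamma <= 1.25:
        raise ValueError(f"gamma must be in [0.75, 1.25], got {gamma}")
    image = validate_image(image)
    r = image.astype(np.float64) / 255.0
    return _finalize(255.0 * np.power(r, 1.0 / gamma))


def apply_color_jitter(
    image: np.ndarray, h_shift: float, s_shift: float, v_shift: float
) -> np.ndarray:
    """Shift hue, saturation and value in 8-bit HSV units (chromatic aberration).

    Hue lives on the half-degree 0-179 scale and wraps; saturation and value
    live on 0-255 and clip.  Each shift must be in [-5, 5].
    """
    for name, s in (("h", h_shift), ("s", s_shift), ("v", v_shift)):
        if not -5.0 <= s <= 5.0:
            raise ValueError(f"{name}_shift must be in [-5, 5], got {s}")
    image = validate_image(image)
    hsv = rgb2hsv(image)  # H, S, V in [0, 1]
    h8 = (hsv[:, :, 0] * 180.0 + h_shift) % 180.0
    s8 = np.clip(hsv[:, :, 1] * 255.0 + s_shift, 0.0, 255.0)
    v8 = np.clip(hsv[:, :, 2] * 255.0 + v_shift, 0.0, 255.0)
    jittered = np.stack([h8 / 180.0, s8 / 255.0, v8 / 255.0], axis=2)
    return _finalize(hsv2rgb(jittered) * 255.0)


def _sample_params(scenario: str, params: dict[str, Any], rng: np.random.Generator) -> dict[str, Any]:
    if scenario == "fog":
        lo, hi = params["intensity"]
        return {"intensity": float(rng.uniform(lo, hi)), "transparency": params["transparency"]}
    if scenario == "gaussian_noise":
        lo, hi = params["variance"]
        return {"variance": float(rng.uniform(lo, hi))}
    if scenario == "defocus":
        lo, hi = params["radius"]
        return {"radius": float(rng.uniform(lo, hi))}
    if scenario == "motion_blur":
        step = params["angle_step_deg"]
        lo, hi = params["length"]
        return {
            "angle_deg": float(step * rng.integers(0, 360 // step)),
            "length_px": int(rng.integers(lo, hi + 1)),
        }
    if scenario == "brightness":
        lo, hi = params["gamma"]
        return {"gamma": float(rng.uniform(lo, hi))}
    lo, hi = params["shift"]
    return {
        "h_shift": float(rng.uniform(lo, hi)),
        "s_shift": float(rng.uniform(lo, hi)),
        "v_shift": float(rng.uniform(lo, hi)),
    }


def apply_scenario(
    image: np.ndarray, scenario: str, sampled: dict[str, Any], rng: np.random.Generator
) -> np.ndarray:
    """Apply one scenario with already-sampled parameters."""
    ops = {
        "fog": lambda: apply_fog(image, rng=rng, **sampled),
        "gaussian_noise": lambda: apply_gaussian_noise(image, rng=rng, **sampled),
        "defocus": lambda: apply_defocus(image, rng=rng, **sampled),
        "motion_blur": lambda: apply_motion_blur(image, rng=rng, **sampled),
        "brightness": lambda: apply_brightness(image, **sampled),
        "color_jitter": lambda: apply_color_jitter(image, **sampled),
    }
    return ops[scenario]()


def corrupt_dataset(
    images: list[np.ndarray],
    scenarios: list[DegradationConfig] | None = None,
    seed: int = 0,
    source_ids: list[str] | None = None,
) -> CorruptedSet:
    """Corrupt every frame under every scenario with per-item derived seeds.

    Produces ``len(images) * len(scenarios)`` frames with provenance records
    (source id, scenario, sampled parameters, derived seed); bit-identical
    across runs for a fixed seed.
    """
    if not images:
        raise ValueError("no input images")
    if scenarios is None:
        scenarios = [DegradationConfig(s) for s in SCENARIOS]
    if source_ids is None:
        source_ids = [f"image_{i:05d}" for i in range(len(images))]
    out_images: list[np.ndarray] = []
    provenance: list[dict[str, Any]] = []
    for i, image in enumerate(images):
        for j, cfg in enumerate(scenarios):
            ss = np.random.SeedSequence([seed, cfg.seed, i, j])
            derived = int(ss.generate_state(1, np.uint32)[0] % (2**31))
            rng = np.random.default_rng(derived)
            sampled = _sample_params(cfg.scenario, cfg.params, rng)
            out_images.append(apply_scenario(image, cfg.scenario, sampled, rng))
            provenance.append(
                {"source": source_ids[i], "scenario": cfg.scenario, "params": sampled, "seed": derived}
            )
    return CorruptedSet(images=out_images, provenance=provenance)
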