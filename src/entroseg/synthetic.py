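"""Seeded generators of images with exact ground truth.

These fixtures emulate the statistical structure the entropy criteria
assume: two pixel populations (background/foreground) with distinct mean
intensities, optionally Gaussian-perturbed, laid out in a simple geometry.
Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import BinaryMask, GrayImage

__all__ = ["FixtureSpec", "make_two_region_constant", "make_bimodal",
           "add_gaussian_noise"]


@dataclass(frozen=True)
class FixtureSpec:
    """Bimodal-image recipe.

    Default populations N(60, 15) background / N(190, 15) foreground on a
    128 x 128 grid: modes separated by more than 4 combined standard
    deviations, giving a clearly bimodal histogram with a near-empty
    valley.  ``noise_sigma`` is on the unit intensity scale [0, 1].
    """

    shape: tuple[int, int] = (128, 128)
    bg_mean: float = 60.0
    bg_std: float = 15.0
    fg_mean: float = 190.0
    fg_std: float = 15.0
    geometry: str = "rectangle"  # rectangle | disk | half_plane
    area_fraction: float = 0.25
    noise_sigma: float = 0.0
    seed: int = 0
    max_level: int = 255

    def __post_init__(self) -> None:
        if not (0 <= self.bg_mean <= self.max_level
                and 0 <= self.fg_mean <= self.max_level):
            raise ValueError("means must lie in [0, max_level]")
        if not 0 < self.area_fraction < 1:
            raise ValueError("area_fraction must be in (0, 1)")
        if self.bg_std < 0 or self.fg_std < 0 or self.noise_sigma < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.geometry not in ("rectangle", "disk", "half_plane"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


def _geometry_mask(spec: FixtureSpec) -> np.ndarray:
    n, m = spec.shape
    if spec.geometry == "half_plane":
        cols = int(round(m * spec.area_fraction))
        mask = np.zeros((n, m), dtype=bool)
        mask[:, m - cols:] = True
        return mask
    if spec.geometry == "rectangle":
        # centered rectangle with the requested area, aspect following the image
        frac = np.sqrt(spec.area_fraction)
        hh, hw = int(round(n * frac / 2)), int(round(m * frac / 2))
        mask = np.zeros((n, m), dtype=bool)
        mask[n // 2 - hh: n // 2 + hh, m // 2 - hw: m // 2 + hw] = True
        return mask
    # disk
    radius = np.sqrt(spec.area_fraction * n * m / np.pi)
    yy, xx = np.mgrid[0:n, 0:m]
    return ((yy - (n - 1) / 2) ** 2 + (xx - (m - 1) / 2) ** 2) <= radius ** 2


def make_two_region_constant(shape: tuple[int, int], v0: int, v1: int,
                             max_level: int = 255
                             ) -> tuple[GrayImage, BinaryMask]:
    """Left half constant v0 (background), right half v1 (foreground)."""
    if not 0 <= v0 < v1 <= max_level:
        raise ValueError("need 0 <= v0 < v1 <= max_level")
    n, m = shape
    px = np.full((n, m), v0, dtype=np.int64)
    px[:, m // 2:] = v1
    return (GrayImage(px, max_level=max_level),
            BinaryMask(px == v1))


def make_bimodal(spec: FixtureSpec) -> tuple[GrayImage, BinaryMask]:
    """Per-pixel normal draws from each region's law, rounded and clamped."""
    rng = np.random.default_rng(spec.seed)
    fg = _geometry_mask(spec)
    n, m = spec.shape
    px = rng.normal(spec.bg_mean, spec.bg_std, size=(n, m)) if spec.bg_std > 0 \
        else np.full((n, m), spec.bg_mean)
    fg_vals = rng.normal(spec.fg_mean, spec.fg_std, size=(n, m)) if spec.fg_std > 0 \
        else np.full((n, m), spec.fg_mean)
    px = np.where(fg, fg_vals, px)
    px = np.clip(np.rint(px), 0, spec.max_level).astype(np.int64)
    img = GrayImage(px, max_level=spec.max_level)
    if spec.noise_sigma > 0:
        img = add_gaussian_noise(img, spec.noise_sigma, seed=spec.seed + 1)
    return img, BinaryMask(fg)


def add_gaussian_noise(img: GrayImage, sigma: float, seed: int) -> GrayImage:
    """Additive Gaussian noise on the unit intensity scale.

    Pixels are rescaled to [0, 1], perturbed by N(0, sigma), rescaled back,
    rounded and clamped.  sigma = 0 returns the image unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return img
    rng = np.random.default_rng(seed)
    unit = img.pixels / img.max_level
    noisy = unit + rng.normal(0.0, sigma, size=img.shape)
    out = np.clip(np.rint(noisy * img.max_level), 0, img.max_level)
    return GrayImage(out.astype(np.int64), max_level=img.max_level)
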