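"""Grayscale image model, histogram, class splitting and binarization.

The whole package works on a single statistic of the image: the gray-level
histogram ``p_0 .. p_L``.  A threshold ``t`` splits the levels into a
background class A (levels ``0..t``) and a foreground class B (levels
``t+1..L``); all entropy criteria consume the two renormalized class
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "GrayImage",
    "BinaryMask",
    "Histogram",
    "ClassSplit",
    "DegenerateSplitError",
    "compute_histogram",
    "split_classes",
    "binarize",
    "to_grayscale",
    "read_image",
    "read_mask",
    "write_mask",
    "write_image",
]

#: BT.601 luma weights for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


class DegenerateSplitError(ValueError):
    """Raised when a threshold leaves one class with zero probability mass."""


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grid of integer intensities in ``[0, max_level]``.

    ``max_level`` defaults to 255 (8-bit) but is carried as data so deeper
    images are admissible.
    """

    pixels: np.ndarray
    max_level: int = 255

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.issubdtype(px.dtype, np.integer):
            raise TypeError("pixels must be integer-valued")
        if px.min() < 0 or px.max() > self.max_level:
            raise ValueError(
                f"pixel values must lie in [0, {self.max_level}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryMask:
    """Background/foreground labels; ``True`` marks foreground pixels."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be 2-D")
        object.__setattr__(self, "labels", lab.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def foreground(self) -> np.ndarray:
        return self.labels

    @property
    def background(self) -> np.ndarray:
        return ~self.labels

    def invert(self) -> "BinaryMask":
        return BinaryMask(~self.labels)


@dataclass(frozen=True)
class Histogram:
    """Per-level counts and probabilities for levels ``0..max_level``."""

    counts: np.ndarray
    probs: np.ndarray
    total_pixels: int
    max_level: int = 255

    @property
    def occupied_levels(self) -> np.ndarray:
        return np.flatnonzero(self.counts)


@dataclass(frozen=True)
class ClassSplit:
    """Threshold split of a histogram: masses and normalized distributions.

    ``dist_a`` covers levels ``0..t`` (background A), ``dist_b`` covers
    levels ``t+1..max_level`` (foreground B).
    """

    t: int
    p_a: float
    p_b: float
    dist_a: np.ndarray
    dist_b: np.ndarray


def compute_histogram(img: GrayImage) -> Histogram:
    """Tally gray levels into a :class:`Histogram`."""
    counts = np.bincount(img.pixels.ravel(), minlength=img.max_level + 1)
    total = int(counts.sum())
    probs = counts / total
    return Histogram(counts=counts, probs=probs, total_pixels=total,
                     max_level=img.max_level)


def split_classes(h: Histogram, t: int) -> ClassSplit:
    """Split histogram into classes A (levels <= t) and B (levels > t).

    Raises
    ------
    DegenerateSplitError
        If either class has zero mass; callers treat such ``t`` as an
        invalid threshold candidate.
    """
    if not 0 <= t < h.max_level:
        raise ValueError(f"threshold {t} outside [0, {h.max_level - 1}]")
    count_a = int(h.counts[: t + 1].sum())
    count_b = h.total_pixels - count_a
    if count_a == 0 or count_b == 0:
        raise DegenerateSplitError(f"empty class at t={t}")
    p_a = count_a / h.total_pixels
    p_b = count_b / h.total_pixels
    return ClassSplit(
        t=t,
        p_a=p_a,
        p_b=p_b,
        dist_a=h.probs[: t + 1] / p_a,
        dist_b=h.probs[t + 1:] / p_b,
    )


def binarize(img: GrayImage, t: int, invert: bool = False) -> BinaryMask:
    """Label pixels with value > t as foreground, <= t as background.

    ``invert=True`` swaps the labels (dark-object images).
    """
    if not 0 <= t <= img.max_level:
        raise ValueError(f"threshold {t} outside [0, {img.max_level}]")
    fg = img.pixels > t
    if invert:
        fg = ~fg
    return BinaryMask(fg)


def to_grayscale(rgb: np.ndarray, max_level: int = 255) -> GrayImage:
    """Convert an RGB array to gray via BT.601 luma, round-half-up."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB array")
    luma = np.floor(rgb.astype(float) @ _LUMA + 0.5)
    return GrayImage(np.clip(luma, 0, max_level).astype(np.int64),
                     max_level=max_level)


def read_image(path: str | Path, max_level: int = 255) -> GrayImage:
    """Read a PNG/TIFF/PGM image as grayscale (RGB converted via luma)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[..., :3]
        return to_grayscale(arr, max_level=max_level)
    return GrayImage(arr.astype(np.int64), max_level=max_level)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a binary mask; any nonzero pixel is foreground."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return BinaryMask(arr > 0)


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    """Write a mask as a 0/255 single-channel image."""
    iio.imwrite(path, (mask.labels.astype(np.uint8) * 255))


def write_image(path: str | Path, img: GrayImage) -> None:
    dtype = np.uint8 if img.max_level <= 255 else np.uint16
    iio.imwrite(path, img.pixels.astype(dtype))
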