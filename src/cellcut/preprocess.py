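"""Preprocessing of grayscale microscopy images into clean binary cell masks.

The chain is: linear contrast stretch -> background normalization ->
Otsu binarization -> small-object removal -> connected-component labeling.
All downstream graph construction operates on the labeled components
produced here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

log = logging.getLogger(__name__)

#: 3x3 structuring element: blob objects are 8-connected throughout.
STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass
class GrayImage:
    """A 2-D grayscale intensity image.

    Parameters
    ----------
    pixels
        2-D array of non-negative integer intensities.
    bit_depth
        8 or 16; intensities must lie in ``[0, 2**bit_depth - 1]``.
    pixel_size_um
        Optional physical pixel size ``(height_um, width_um)``, used by the
        evaluation layer to convert a matching radius given in micrometers.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    pixel_size_um: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("GrayImage requires a nonempty 2-D array")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixels.min() < 0 or self.pixels.max() > self.max_level:
            raise ValueError(
                f"intensities outside [0, {self.max_level}] for bit depth {self.bit_depth}"
            )

    @property
    def max_level(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """Boolean foreground mask on the same grid as its source image."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("BinaryMask requires a 2-D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabeledComponents:
    """Integer-labeled 8-connected foreground components.

    ``labels`` uses 0 for background and 1..count for components; ``areas[k]``
    and ``bounding_boxes[k]`` describe label ``k + 1`` (half-open row/col
    ranges).
    """

    labels: np.ndarray
    count: int
    areas: np.ndarray = field(repr=False)
    bounding_boxes: list[tuple[int, int, int, int]] = field(repr=False)


def enhance_linear_stretch(img: GrayImage) -> GrayImage:
    """Stretch intensities affinely so the extrema span the full bit range.

    A constant image is returned unchanged (with a warning) since the affine
    map is undefined there.  Rounding is half-up to the nearest level, so the
    map is deterministic and order-preserving.
    """
    pixels = img.pixels
    r_min = int(pixels.min())
    r_max = int(pixels.max())
    if r_min == r_max:
        warnings.warn("constant image: linear stretch skipped", stacklevel=2)
        return GrayImage(pixels.copy(), img.bit_depth, img.pixel_size_um)
    scale = img.max_level / (r_max - r_min)
    stretched = (pixels.astype(np.float64) - r_min) * scale
    # round-half-up, not banker's rounding
    out = np.floor(stretched + 0.5).astype(np.uint8 if img.bit_depth == 8 else np.uint16)
    return GrayImage(out, img.bit_depth, img.pixel_size_um)


def subtract_background(
    img: GrayImage,
    polarity: str = "light_cells",
    flat_background: bool = False,
) -> GrayImage:
    """Normalize polarity so that cells are bright on a dark background.

    ``polarity='dark_cells'`` (Nissl-style absorption images) inverts the
    intensities; ``'light_cells'`` (fluorescence-style) passes through.  With
    ``flat_background=True`` the median intensity is additionally subtracted
    and the result clamped at zero, flattening a uniform background offset.
    """
    if polarity not in ("light_cells", "dark_cells"):
        raise ValueError(f"unknown polarity {polarity!r}")
    pixels = img.pixels.astype(np.int64)
    if polarity == "dark_cells":
        pixels = img.max_level - pixels
    if flat_background:
        pixels = np.maximum(pixels - int(np.median(pixels)), 0)
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    return GrayImage(pixels.astype(dtype), img.bit_depth, img.pixel_size_um)


def otsu_binarize(img: GrayImage) -> BinaryMask:
    """Threshold at the maximizer of between-class variance (Otsu).

    Pixels strictly above the threshold become foreground; cells are assumed
    brighter than background (apply :func:`subtract_background` first for
    dark-cell images).  A constant image yields an all-background mask.
    """
    pixels = img.pixels
    if pixels.min() == pixels.max():
        warnings.warn("constant image: empty foreground from Otsu", stacklevel=2)
        return BinaryMask(np.zeros(img.shape, dtype=bool))
    t = threshold_otsu(pixels, nbins=img.max_level + 1)
    return BinaryMask(pixels > t)


def remove_small_components(mask: BinaryMask, min_area: int) -> BinaryMask:
    """Drop 8-connected foreground components with fewer than ``min_area`` px."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    if min_area <= 1:
        return BinaryMask(mask.pixels.copy())
    labels, n = ndimage.label(mask.pixels, structure=STRUCTURE_8)
    if n == 0:
        return BinaryMask(mask.pixels.copy())
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    keep = areas >= min_area
    keep[0] = False
    return BinaryMask(keep[labels])


def label_components(mask: BinaryMask) -> LabeledComponents:
    """Label 8-connected foreground components contiguously from 1."""
    labels, n = ndimage.label(mask.pixels, structure=STRUCTURE_8)
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:] if n else np.zeros(0, int)
    slices = ndimage.find_objects(labels) if n else []
    boxes = [(s[0].start, s[0].stop, s[1].start, s[1].stop) for s in slices]
    return LabeledComponents(labels=labels, count=n, areas=areas, bounding_boxes=boxes)
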