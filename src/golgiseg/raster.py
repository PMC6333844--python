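"""Bit-depth-aware raster primitives.

The stained-neuron segmentation pipeline is built from a handful of simple
operations on 2D rasters: dark/bright thresholding, binary morphology with a
circular (Euclidean disc) structuring element, separable Gaussian smoothing,
8-connected region labeling and area filtering.  Everything here is pure and
in-memory: images are NumPy arrays, binary masks are boolean arrays of the
same shape, and bit depth ``b`` (8 or 16) only enters where values are
materialized onto the ``0 .. 2**b - 1`` intensity scale.

Conventions (they matter for reproducibility and are relied on by callers):

* disc structuring element = all integer offsets with ``dy**2 + dx**2 <= r**2``;
* dilation treats out-of-frame pixels as background, erosion as foreground,
  so closing is extensive even at the frame border and never eats staining
  that touches the edge of the field of view;
* the Gaussian kernel is the continuous ``G(x, y)`` sampled on the integer
  lattice, truncated at radius ``ceil(3 * sigma)``, renormalized to unit sum,
  applied separably with mirror-reflect border handling (mass-conserving);
* ``threshold_dark`` keeps values ``<= t1`` and ``threshold_bright`` keeps
  values ``>= t2`` (both boundaries inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure


class ParameterRangeError(ValueError):
    """A segmentation parameter lies outside its admissible range."""


class InputFormatError(ValueError):
    """An input image or stack violates the expected format."""


def max_intensity(bit_depth: int) -> int:
    """Maximum representable intensity ``2**b - 1`` for bit depth ``b``."""
    if bit_depth not in (8, 16):
        raise InputFormatError(f"bit depth must be 8 or 16, got {bit_depth}")
    return (1 << bit_depth) - 1


def _check_intensity(value: float, bit_depth: int, name: str) -> None:
    hi = max_intensity(bit_depth)
    if not 0 <= value <= hi:
        raise ParameterRangeError(f"{name}={value} outside [0, {hi}] for {bit_depth}-bit data")


# ---------------------------------------------------------------------------
# structuring element


@dataclass(frozen=True)
class StructuringElement:
    """Euclidean-disc structuring element of integer radius ``radius``.

    ``footprint`` is the ``(2r+1, 2r+1)`` boolean array with True exactly at
    offsets ``(dy, dx)`` with ``dy**2 + dx**2 <= radius**2``; it is symmetric
    and contains the origin.
    """

    radius: int
    footprint: np.ndarray = field(compare=False)

    def __init__(self, radius: int):
        if radius < 0:
            raise ParameterRangeError(f"structuring-element radius must be >= 0, got {radius}")
        object.__setattr__(self, "radius", int(radius))
        dy, dx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
        object.__setattr__(self, "footprint", dy * dy + dx * dx <= radius * radius)

    @property
    def offsets(self) -> set[tuple[int, int]]:
        r = self.radius
        ys, xs = np.nonzero(self.footprint)
        return {(int(y) - r, int(x) - r) for y, x in zip(ys, xs)}


def disc(radius: int) -> StructuringElement:
    """Circular structuring element with the given pixel radius."""
    return StructuringElement(radius)


# ---------------------------------------------------------------------------
# thresholding


def threshold_dark(image: np.ndarray, t1: float, bit_depth: int) -> np.ndarray:
    """Select stain-dark pixels: True where intensity ``<= t1``.

    Gold/silver granules are far darker than tissue background, so the first
    pipeline stage keeps every pixel between 0 and ``t1`` inclusive.
    """
    _check_intensity(t1, bit_depth, "max_stain_intensity (T1)")
    return np.asarray(image) <= t1


def threshold_bright(image: np.ndarray, t2: float, bit_depth: int) -> np.ndarray:
    """Select region pixels after smoothing: True where value ``>= t2``."""
    _check_intensity(t2, bit_depth, "min_segment_intensity (T2)")
    return np.asarray(image) >= t2


def materialize(mask: np.ndarray, bit_depth: int) -> np.ndarray:
    """Render a boolean mask onto the intensity scale: True -> 2**b - 1, False -> 0."""
    hi = max_intensity(bit_depth)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return np.where(np.asarray(mask, dtype=bool), hi, 0).astype(dtype)


# ---------------------------------------------------------------------------
# binary morphology


def _as_se(se: StructuringElement | int) -> StructuringElement:
    return se if isinstance(se, StructuringElement) else StructuringElement(se)


def dilate(mask: np.ndarray, se: StructuringElement | int) -> np.ndarray:
    """Binary dilation by a disc; out-of-frame counts as background."""
    se = _as_se(se)
    if se.radius == 0:
        return np.asarray(mask, dtype=bool).copy()
    return ndimage.binary_dilation(mask, structure=se.footprint, border_value=0)


def erode(mask: np.ndarray, se: StructuringElement | int) -> np.ndarray:
    """Binary erosion by a disc; out-of-frame counts as foreground.

    The foreground border convention keeps closing extensive on the frame, so
    neurites exiting the field of view are not artificially eroded away.
    """
    se = _as_se(se)
    if se.radius == 0:
        return np.asarray(mask, dtype=bool).copy()
    return ndimage.binary_erosion(mask, structure=se.footprint, border_value=1)


def close(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological closing (dilation then erosion with the same disc).

    Bridges gaps between nearby stained granules: particles within roughly
    ``2 * radius`` of one another are merged into one region.  Extensive and
    idempotent; ``radius == 0`` is the identity.
    """
    if radius < 0:
        raise ParameterRangeError(f"close radius must be >= 0, got {radius}")
    if radius == 0:
        return np.asarray(mask, dtype=bool).copy()
    se = StructuringElement(radius)
    return erode(dilate(mask, se), se)


# ---------------------------------------------------------------------------
# Gaussian smoothing


def gaussian_kernel(sigma: float) -> np.ndarray:
    """1D kernel sampling exp(-x^2 / (2 sigma^2)) at integers |x| <= ceil(3 sigma),
    renormalized to unit sum."""
    if sigma < 0:
        raise ParameterRangeError(f"blur sigma must be >= 0, got {sigma}")
    radius = math.ceil(3 * sigma)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-(x * x) / (2.0 * sigma * sigma))
    return k / k.sum()


def gaussian_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian smoothing with mirror-reflect borders.

    Returns float64.  ``sigma == 0`` returns the input unchanged (as float).
    The unit-sum kernel plus symmetric border handling conserves total image
    mass to floating-point precision, which keeps the second threshold stage
    scale-stable near frame borders.
    """
    img = np.asarray(image, dtype=np.float64)
    if sigma < 0:
        raise ParameterRangeError(f"blur sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return img.copy()
    k = gaussian_kernel(sigma)
    out = ndimage.correlate1d(img, k, axis=0, mode="reflect")
    out = ndimage.correlate1d(out, k, axis=1, mode="reflect")
    return out


# ---------------------------------------------------------------------------
# region labeling and area filtering


@dataclass(frozen=True)
class RegionLabeling:
    """8-connected labeling of a binary mask.

    ``labels`` has 0 for background and contiguous labels 1..n in raster-scan
    order of first appearance; ``region_areas`` maps each label to its pixel
    count.
    """

    labels: np.ndarray
    region_areas: dict[int, int]

    @property
    def n_regions(self) -> int:
        return len(self.region_areas)


def label_regions(mask: np.ndarray) -> RegionLabeling:
    """Label 8-connected foreground regions of a binary mask."""
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    counts = np.bincount(labels.ravel())
    areas = {int(lab): int(counts[lab]) for lab in range(1, len(counts))}
    return RegionLabeling(labels=labels, region_areas=areas)


def filter_regions_by_area(labeling: RegionLabeling, min_size: int) -> np.ndarray:
    """Keep regions with area >= ``min_size`` pixels; returns a boolean mask.

    With ``min_size == 0`` the filter is vacuous and returns the labeling's
    full foreground, which is the recommended starting point when tuning so
    no genuine staining is suppressed by accident.
    """
    if min_size < 0:
        raise ParameterRangeError(f"min segment size must be >= 0, got {min_size}")
    labels = labeling.labels
    n = int(labels.max())
    keep = np.zeros(n + 1, dtype=bool)
    for lab, area in labeling.region_areas.items():
        keep[lab] = area >= min_size
    keep[0] = False
    return keep[labels]
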