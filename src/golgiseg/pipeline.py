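"""The stained-neuron segmentation pipeline.

Golgi-impregnated, gold-toned neurons appear in serial EM images as clusters
of very dark granules on a lighter tissue background.  Thresholding alone
yields unconnected groups of dots — one per grain — so the segmenter chains
six simple stages to turn those dots into contiguous per-neuron regions:

1. dark threshold at T1 (``max_stain_intensity``): grains are the darkest
   objects in the image, so every pixel with intensity <= T1 is foreground;
2. morphological closing with a circular element (``close_radius``): grains
   within ~2r of each other merge into one region, holes are filled;
3. Gaussian blur (``blur_sigma``) of the materialized binary image: closing
   leaves hard, jagged contours, smoothing rounds them;
4. bright threshold at T2 (``min_segment_intensity``) on the blurred image:
   recovers a binary mask with smooth boundaries; small T2 pushes boundaries
   out, large T2 pulls them in and can disconnect regions;
5. area filter (``min_segment_size``): isolated regions below the minimum
   area — typically non-specific staining — are discarded;
6. output as a binary mask stack, a two-channel composite (original + mask),
   or a red preview overlay.

Each slice of a stack is segmented independently in 2D; 3D association is a
separate stage (see :mod:`golgiseg.volume`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import raster
from .raster import InputFormatError, ParameterRangeError
from .stack import ImageStack


@dataclass(frozen=True)
class SegmentationParams:
    """The published parameter set governing the pipeline.

    Intensity thresholds are on the input's own ``0 .. 2**b - 1`` scale.
    There are deliberately no defaults for the five stage parameters: start
    with ``min_segment_intensity = 1`` and ``min_segment_size = 0``, obtain a
    reasonable segmentation, then raise them gradually.
    """

    max_stain_intensity: float  # T1: pixels in [0, T1] are staining particles
    close_radius: int  # extent of morphological closing, pixels
    blur_sigma: float  # Gaussian sigma, pixels
    min_segment_intensity: float  # T2: threshold on the blurred image
    min_segment_size: int  # minimum region area, pixels
    mask_only: bool = False  # binary mask output vs two-channel composite
    preview_opacity: int = 50  # overlay opacity, percent
    preview_slice: int = 1  # 1-based slice index used for preview

    def validate(self, bit_depth: int, n_slices: int | None = None) -> None:
        hi = raster.max_intensity(bit_depth)
        if not 0 <= self.max_stain_intensity <= hi:
            raise ParameterRangeError(
                f"max_stain_intensity={self.max_stain_intensity} outside [0, {hi}]"
            )
        if not 0 <= self.min_segment_intensity <= hi:
            raise ParameterRangeError(
                f"min_segment_intensity={self.min_segment_intensity} outside [0, {hi}]"
            )
        if self.close_radius < 0:
            raise ParameterRangeError(f"close_radius={self.close_radius} must be >= 0")
        if self.blur_sigma < 0:
            raise ParameterRangeError(f"blur_sigma={self.blur_sigma} must be >= 0")
        if self.min_segment_size < 0:
            raise ParameterRangeError(f"min_segment_size={self.min_segment_size} must be >= 0")
        if not 0 <= self.preview_opacity <= 100:
            raise ParameterRangeError(f"preview_opacity={self.preview_opacity} outside [0, 100]")
        if n_slices is not None and not 1 <= self.preview_slice <= n_slices:
            raise ParameterRangeError(
                f"preview_slice={self.preview_slice} outside [1, {n_slices}]"
            )


@dataclass(frozen=True)
class SegmentationResult:
    """Output of :func:`segment_stack`.

    ``mask_stack`` is the boolean per-slice mask volume.  ``composite`` is
    the two-channel output — channel 1 the untouched original data, channel 2
    the mask materialized at 0 / 2**b - 1 — present exactly when
    ``mask_only`` is False.
    """

    mask_stack: np.ndarray  # bool, (slices, h, w)
    composite: tuple[np.ndarray, np.ndarray] | None
    params_used: SegmentationParams
    per_slice_region_counts: tuple[int, ...]


def segment_slice(image: np.ndarray, params: SegmentationParams, bit_depth: int) -> np.ndarray:
    """Run the five raster stages on one 2D slice; returns a boolean mask."""
    params.validate(bit_depth)
    dark = raster.threshold_dark(image, params.max_stain_intensity, bit_depth)
    closed = raster.close(dark, params.close_radius)
    blurred = raster.gaussian_blur(raster.materialize(closed, bit_depth), params.blur_sigma)
    bright = raster.threshold_bright(blurred, params.min_segment_intensity, bit_depth)
    labeling = raster.label_regions(bright)
    return raster.filter_regions_by_area(labeling, params.min_segment_size)


def segment_stack(stack: ImageStack, params: SegmentationParams) -> SegmentationResult:
    """Segment every slice of a stack independently.

    Slices are processed in 2D exactly as :func:`segment_slice` would; the
    result is deterministic and slice-independent (segmenting a sub-stack
    gives the corresponding sub-sequence of masks).
    """
    if not isinstance(stack, ImageStack):
        stack = ImageStack(stack)
    if stack.n_slices < 1:
        raise InputFormatError("empty stack")
    params.validate(stack.bit_depth, n_slices=stack.n_slices)
    masks = np.empty(stack.shape, dtype=bool)
    counts = []
    for i in range(stack.n_slices):
        mask = segment_slice(stack[i], params, stack.bit_depth)
        masks[i] = mask
        counts.append(raster.label_regions(mask).n_regions)
    composite = None
    if not params.mask_only:
        mask_channel = raster.materialize(masks, stack.bit_depth)
        composite = (stack.data.copy(), mask_channel)
    return SegmentationResult(
        mask_stack=masks,
        composite=composite,
        params_used=replace(params),
        per_slice_region_counts=tuple(counts),
    )


def _to_display_gray(image: np.ndarray, bit_depth: int) -> np.ndarray:
    """Rescale grays to the 8-bit display range (16-bit: v*255/65535, half-up)."""
    if bit_depth == 8:
        return np.asarray(image, dtype=np.float64)
    return np.floor(np.asarray(image, np.float64) * 255.0 / raster.max_intensity(16) + 0.5)


def render_overlay(
    image: np.ndarray, mask: np.ndarray, opacity_percent: int, bit_depth: int
) -> np.ndarray:
    """Red segmentation overlay on the grayscale slice; returns (h, w, 3) uint8.

    Mask pixels are alpha-blended with pure red: per channel
    ``out = (1 - a) * gray + a * red`` with ``a = opacity_percent / 100`` and
    red = (255, 0, 0); values round half-up.  Display-only: 16-bit grays are
    rescaled to 8-bit for rendering, the data itself is never rescaled.
    """
    if not 0 <= opacity_percent <= 100:
        raise ParameterRangeError(f"preview_opacity={opacity_percent} outside [0, 100]")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != np.asarray(image).shape:
        raise InputFormatError("mask shape does not match slice shape")
    gray = _to_display_gray(image, bit_depth)
    alpha = opacity_percent / 100.0
    rgb = np.repeat(gray[..., np.newaxis], 3, axis=-1)
    red = np.array([255.0, 0.0, 0.0])
    rgb[mask] = (1.0 - alpha) * rgb[mask] + alpha * red
    return np.floor(rgb + 0.5).astype(np.uint8)


def preview(stack: ImageStack, params: SegmentationParams) -> np.ndarray:
    """Segmentation preview: red overlay on the 1-based ``preview_slice``."""
    if not isinstance(stack, ImageStack):
        stack = ImageStack(stack)
    params.validate(stack.bit_depth, n_slices=stack.n_slices)
    image = stack[params.preview_slice - 1]
    mask = segment_slice(image, params, stack.bit_depth)
    return render_overlay(image, mask, params.preview_opacity, stack.bit_depth)
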