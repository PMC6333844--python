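"""Synthetic phantoms emulating Golgi/gold-toned EM staining.

Real validation data for this kind of segmentation is a serial block-face EM
stack of an impregnated neuron: clusters of very dark metal granules of
variable size and density scattered through a neurite, on a brighter,
texture-noisy tissue background, plus occasional isolated non-specific
grains.  The phantom generator reproduces exactly the features the pipeline
keys on, with known ground truth:

* a tubular neurite of radius ``tube_radius`` whose centerline runs across
  the full lateral field in every slice — a smoothed random walk in-plane,
  drifting smoothly in z across slices, the geometry of a neurite lying
  nearly parallel to the cutting plane (the case that actually requires
  cross-slice tracing at a 200 nm step);
* dark granules stamped wholly inside the tube, with per-slice Poisson
  counts set by ``granule_density`` granules per 100 tube pixels (pixels of
  that slice's tube cross-section), radii uniform in
  ``granule_radius_range`` and per-pixel intensities from a clipped normal;
  the default density emulates a densely impregnated neurite, while low
  densities (roughly 5-8 per 100 tube pixels) produce the sparse
  unconnected-dots regime in which plain thresholding fragments the neuron;
* ``nonspecific_density`` isolated granules per slice placed far from the
  tube, emulating non-specific background staining;
* the ground-truth mask is exactly the set of pixels within ``tube_radius``
  of the recorded centerline, slice by slice.

A single seeded generator drives every stochastic draw in a fixed,
documented order (path, z-drift, then per slice: background, tube granules,
non-specific granules), so identical (spec, seed) always yields bit-identical
phantoms and adding draws for one feature cannot silently shift another.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .raster import InputFormatError, StructuringElement, max_intensity
from .stack import ImageStack

#: Stamp-time geometry margins (pixels): non-specific granules are kept at
#: least this far from the tube centerline / each other / the frame border so
#: they remain isolated objects through closing and blurring.
_NONSPECIFIC_TUBE_CLEARANCE = 24
_NONSPECIFIC_PAIR_CLEARANCE = 24
_NONSPECIFIC_BORDER_MARGIN = 8


class PhantomSpecError(ValueError):
    """A phantom specification violates its invariants."""


@dataclass(frozen=True)
class PhantomSpec:
    """Configuration of one synthetic stack.

    Intensities are on the ``0 .. 2**bit_depth - 1`` scale.  The defaults
    describe an 8-bit stack whose granule and background intensity bands are
    well separated (granule mean 20 +- 8 vs background 180 +- 12), the regime
    a correctly exposed gold-toned EM image presents.
    """

    shape: tuple[int, int, int] = (8, 256, 256)  # (slices, height, width)
    bit_depth: int = 8
    seed: int = 0
    background_mean: float = 180.0
    background_sd: float = 12.0
    path_waviness: float = 1.0  # std of the centerline walk step before smoothing
    tube_radius: int = 6
    granule_density: float = 35.0  # expected granules per 100 tube pixels
    granule_radius_range: tuple[float, float] = (1.0, 3.0)
    granule_mean: float = 20.0
    granule_sd: float = 8.0
    nonspecific_density: float = 3.0  # expected isolated granules per slice

    def validate(self) -> None:
        hi = max_intensity(self.bit_depth)
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise PhantomSpecError(f"shape must be 3 positive ints, got {self.shape}")
        for name in ("background_mean", "granule_mean"):
            v = getattr(self, name)
            if not 0 <= v <= hi:
                raise PhantomSpecError(f"{name}={v} outside [0, {hi}]")
        if self.granule_mean + 3 * self.granule_sd >= self.background_mean - 3 * self.background_sd:
            raise PhantomSpecError(
                "granule and background intensity bands overlap: require "
                "granule_mean + 3*granule_sd < background_mean - 3*background_sd"
            )
        if self.tube_radius < 1:
            raise PhantomSpecError(f"tube_radius={self.tube_radius} must be >= 1")
        rmin, rmax = self.granule_radius_range
        if not 0 < rmin <= rmax:
            raise PhantomSpecError(f"bad granule_radius_range {self.granule_radius_range}")
        if rmax >= self.tube_radius + 1:
            raise PhantomSpecError("granule radius must not exceed the tube radius")
        if self.granule_density < 0 or self.nonspecific_density < 0:
            raise PhantomSpecError("densities must be >= 0")
        if self.background_sd < 0 or self.granule_sd < 0 or self.path_waviness < 0:
            raise PhantomSpecError("spread parameters must be >= 0")


@dataclass(frozen=True)
class Phantom:
    """A generated stack with its ground truth.

    ``path_record[z]`` holds the slice-z centerline as an ``(width, 2)``
    array of (y, x) pixel coordinates, one point per column; ``truth_mask``
    is exactly the union of ``tube_radius``-discs around those points.
    ``nonspecific_centers`` records every stamped non-specific granule as
    (z, y, x), so exclusion of isolated non-specific staining from a
    segmentation can be audited directly.
    """

    stack: ImageStack
    truth_mask: np.ndarray  # bool, stack shape
    path_record: np.ndarray  # int, (slices, width, 2), (y, x)
    spec_used: PhantomSpec
    nonspecific_centers: tuple[tuple[int, int, int], ...] = ()


def _disc_points(radius: float) -> np.ndarray:
    """Integer offsets (dy, dx) with dy^2 + dx^2 <= radius^2, as an (n, 2) array."""
    r = int(np.floor(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy * dy + dx * dx <= radius * radius
    return np.stack([dy[keep], dx[keep]], axis=1)


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate a phantom stack; bit-identical for identical (spec, seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_slices, height, width = spec.shape
    hi = max_intensity(spec.bit_depth)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    rho = spec.tube_radius

    # --- draw 1: in-plane centerline, a smoothed random walk across x
    steps = rng.normal(0.0, spec.path_waviness, size=width)
    y_base = ndimage.gaussian_filter1d(np.cumsum(steps), sigma=16.0, mode="reflect")
    y_base += height / 2.0 - y_base.mean()
    # --- draw 2: smooth lateral drift of the whole neurite across slices
    drift = np.cumsum(rng.normal(0.0, 1.5, size=n_slices))
    margin = rho + 4
    y_per_slice = np.clip(
        y_base[np.newaxis, :] + drift[:, np.newaxis], margin, height - 1 - margin
    )
    path_y = np.rint(y_per_slice).astype(np.int64)
    xs = np.arange(width, dtype=np.int64)
    path_record = np.stack(
        [path_y, np.broadcast_to(xs, path_y.shape)], axis=-1
    )

    tube_fp = StructuringElement(rho).footprint
    image = np.empty(spec.shape, dtype=dtype)
    truth = np.empty(spec.shape, dtype=bool)
    rmin, rmax = spec.granule_radius_range
    ns_centers: list[tuple[int, int, int]] = []

    for z in range(n_slices):
        # draw 3a: background texture
        bg = rng.normal(spec.background_mean, spec.background_sd, size=(height, width))
        plane = np.clip(np.rint(bg), 0, hi).astype(dtype)

        centerline = np.zeros((height, width), dtype=bool)
        centerline[path_y[z], xs] = True
        truth[z] = ndimage.binary_dilation(centerline, structure=tube_fp, border_value=0)

        # draw 3b: granules along the tube, wholly inside it (metal deposits
        # sit in the impregnated cytoplasm, not outside the membrane);
        # expected count scales with this slice's tube pixel count
        tube_pixels = int(truth[z].sum())
        n_granules = rng.poisson(spec.granule_density * tube_pixels / 100.0)
        for _ in range(n_granules):
            col = int(rng.integers(0, width))
            radius = rng.uniform(rmin, rmax)
            reach = max(rho - radius, 0.0)
            d = reach * np.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * np.pi)
            cy = int(np.rint(path_y[z, col] + d * np.sin(theta)))
            cx = int(np.rint(col + d * np.cos(theta)))
            _stamp_granule(plane, rng, cy, cx, radius, spec, hi)

        # draw 3c: isolated non-specific granules, far from the tube
        n_ns = rng.poisson(spec.nonspecific_density)
        placed: list[tuple[int, int]] = []
        for _ in range(n_ns):
            pos = _place_nonspecific(rng, path_record[z], placed, height, width, rho)
            if pos is None:
                continue
            placed.append(pos)
            ns_centers.append((z, pos[0], pos[1]))
            radius = rng.uniform(rmin, rmax)
            _stamp_granule(plane, rng, pos[0], pos[1], radius, spec, hi)

        image[z] = plane

    return Phantom(
        stack=ImageStack(image),
        truth_mask=truth,
        path_record=path_record,
        spec_used=spec,
        nonspecific_centers=tuple(ns_centers),
    )


def _stamp_granule(plane, rng, cy, cx, radius, spec, hi):
    """Darken a disc of the given radius at (cy, cx); overlaps keep the darker value."""
    pts = _disc_points(radius) + np.array([cy, cx])
    inside = (
        (pts[:, 0] >= 0) & (pts[:, 0] < plane.shape[0])
        & (pts[:, 1] >= 0) & (pts[:, 1] < plane.shape[1])
    )
    pts = pts[inside]
    vals = np.clip(np.rint(rng.normal(spec.granule_mean, spec.granule_sd, len(pts))), 0, hi)
    ys, xs_ = pts[:, 0], pts[:, 1]
    plane[ys, xs_] = np.minimum(plane[ys, xs_], vals.astype(plane.dtype))


def _place_nonspecific(rng, centerline, placed, height, width, rho, max_tries=200):
    """Rejection-sample a position far from the tube, other granules and borders."""
    m = _NONSPECIFIC_BORDER_MARGIN
    for _ in range(max_tries):
        y = int(rng.integers(m, height - m))
        x = int(rng.integers(m, width - m))
        d_tube = np.sqrt(
            (centerline[:, 0] - y) ** 2 + (centerline[:, 1] - x) ** 2
        ).min()
        if d_tube < rho + _NONSPECIFIC_TUBE_CLEARANCE:
            continue
        if any(
            (y - py) ** 2 + (x - px) ** 2 < _NONSPECIFIC_PAIR_CLEARANCE**2
            for py, px in placed
        ):
            continue
        return (y, x)
    return None


def score_against_truth(
    predicted: np.ndarray, truth: np.ndarray
) -> tuple[float, float, float]:
    """(IoU, precision, recall) of a predicted mask against ground truth.

    Counted over all voxels.  Conventions for degenerate masks: if both are
    empty all three scores are 1; an empty prediction against non-empty
    truth scores 0 everywhere (precision's 0/0 is reported as 0); a
    non-empty prediction against empty truth has recall 0.
    """
    p = np.asarray(predicted, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise InputFormatError(f"shape mismatch: predicted {p.shape} vs truth {t.shape}")
    np_, nt = int(p.sum()), int(t.sum())
    if np_ == 0 and nt == 0:
        return (1.0, 1.0, 1.0)
    inter = int((p & t).sum())
    union = np_ + nt - inter
    iou = inter / union
    precision = inter / np_ if np_ else 0.0
    recall = inter / nt if nt else 0.0
    return (iou, precision, recall)


def save_phantom(phantom: Phantom, directory: str | Path) -> dict[str, Path]:
    """Serialize a phantom: image + truth TIFFs and a plain-text metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    image_path = directory / "phantom_image.tif"
    truth_path = directory / "phantom_truth.tif"
    meta_path = directory / "phantom_metadata.txt"
    tifffile.imwrite(image_path, phantom.stack.data, photometric="minisblack")
    tifffile.imwrite(
        truth_path, np.where(phantom.truth_mask, 255, 0).astype(np.uint8),
        photometric="minisblack",
    )
    lines = [f"{k} = {v}" for k, v in asdict(phantom.spec_used).items()]
    meta_path.write_text("\n".join(lines) + "\n")
    return {"image": image_path, "truth": truth_path, "metadata": meta_path}
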