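"""Reading and writing stacks, masks, overlays, label volumes and manifests.

Input is an 8- or 16-bit grayscale TIFF (single page or multi-page
stack); the segmentation
output is either a binary mask stack alone, or the mask paired with an
untouched copy of the original data (the "two-channel" composite,
serialized as two aligned single-channel TIFFs to avoid writer-dependent
hyperstack dialects).  Masks are always written 8-bit at 0/255; the
original-data channel keeps its native depth.  Coordinates in logs and CSV
output are 0-based (z, y, x); only the CLI's ``--preview-slice`` is 1-based,
matching the ImageJ slice-numbering convention.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .pipeline import SegmentationParams, SegmentationResult, render_overlay
from .raster import InputFormatError, materialize
from .stack import ImageStack
from .volume import DEFAULT_VOXEL_SIZE_UM, LabeledVolume, component_stats

logger = logging.getLogger("golgiseg")


@dataclass(frozen=True)
class RunConfig:
    """Everything one segmentation run needs: paths, parameters, options."""

    input_path: Path
    output_dir: Path
    params: SegmentationParams
    link_3d: bool = False
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    overlay_export: bool = False
    log_level: str = "INFO"


def read_stack(path: str | Path) -> ImageStack:
    """Read an 8/16-bit grayscale TIFF (or multi-page stack) into memory.

    Page order is preserved; a single-page image becomes a 1-slice stack.
    RGB, 32-bit or non-TIFF input is rejected with an error naming the
    offending property.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            photometric = tif.pages[0].photometric
            if photometric not in (
                tifffile.PHOTOMETRIC.MINISBLACK,
                tifffile.PHOTOMETRIC.MINISWHITE,
            ):
                raise InputFormatError(
                    f"{path}: photometric {photometric.name} not supported, grayscale required"
                )
            data = tif.asarray()
    except (tifffile.TiffFileError, ValueError) as exc:
        raise InputFormatError(f"cannot parse {path} as TIFF: {exc}") from exc
    data = np.asarray(data)
    if data.ndim not in (2, 3):
        raise InputFormatError(f"{path}: expected 2D image or 3D stack, got ndim={data.ndim}")
    if data.dtype not in (np.uint8, np.uint16):
        raise InputFormatError(
            f"{path}: bit depth {data.dtype} not supported, 8 or 16-bit grayscale required"
        )
    return ImageStack(data)


def write_stack(path: str | Path, data: np.ndarray) -> Path:
    """Write a (slices, h, w) array as a multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # grayscale pages, never RGB (a 3-slice stack is not a color image)
    tifffile.imwrite(path, np.asarray(data), photometric="minisblack")
    return path


def write_mask_stack(path: str | Path, mask_stack: np.ndarray) -> Path:
    """Write a boolean mask stack as 8-bit TIFF materialized at 0/255."""
    return write_stack(path, materialize(np.asarray(mask_stack, dtype=bool), 8))


@dataclass
class Manifest:
    """List of files written by a run, each with its role."""

    entries: list[tuple[str, Path]] = field(default_factory=list)

    def add(self, role: str, path: Path) -> None:
        self.entries.append((role, Path(path)))

    def roles(self) -> list[str]:
        return [role for role, _ in self.entries]

    def path_for(self, role: str) -> Path:
        for r, p in self.entries:
            if r == role:
                return p
        raise KeyError(f"no manifest entry with role {role!r}")

    def write(self, path: Path) -> Path:
        lines = [f"{role}\t{p}" for role, p in self.entries]
        path.write_text("\n".join(lines) + "\n")
        return path


def write_outputs(
    result: SegmentationResult,
    volume: LabeledVolume | None,
    config: RunConfig,
    stack: ImageStack | None = None,
) -> Manifest:
    """Serialize a segmentation run into ``config.output_dir``.

    Always writes the 0/255 mask stack; adds the original-data channel when
    the run is not mask-only, per-slice overlay PNGs when requested, and the
    16-bit label volume plus component CSV when 3D linking ran.  Returns the
    manifest, which is also written as ``manifest.txt``.
    """
    out = Path(config.output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    manifest = Manifest()
    manifest.add("mask", write_mask_stack(out / "mask.tif", result.mask_stack))
    if result.composite is not None:
        original, mask_channel = result.composite
        manifest.add("composite_original", write_stack(out / "composite_original.tif", original))
        manifest.add("composite_mask", write_stack(out / "composite_mask.tif", mask_channel))
    if config.overlay_export:
        if stack is None:
            raise InputFormatError("overlay export requires the input stack")
        for i in range(stack.n_slices):
            rgb = render_overlay(
                stack[i],
                result.mask_stack[i],
                result.params_used.preview_opacity,
                stack.bit_depth,
            )
            p = out / f"overlay_z{i:04d}.png"
            iio.imwrite(p, rgb)
            manifest.add("overlay", p)
    if volume is not None:
        if volume.n_components > np.iinfo(np.uint16).max:
            raise InputFormatError("more than 65535 components; cannot write 16-bit labels")
        manifest.add("labels", write_stack(out / "labels.tif", volume.labels.astype(np.uint16)))
        stats = component_stats(volume)
        stats_path = out / "component_stats.csv"
        stats.to_csv(stats_path, index=False)
        manifest.add("component_stats", stats_path)
    manifest.add("manifest", out / "manifest.txt")
    manifest.write(out / "manifest.txt")
    return manifest


# --- plain-text key=value config files ------------------------------------

_CONFIG_KEYS = {
    "input",
    "output-dir",
    "max-stain-intensity",
    "close-radius",
    "blur-sigma",
    "min-segment-intensity",
    "min-segment-size",
    "mask-only",
    "preview-opacity",
    "preview-slice",
    "link-3d",
    "voxel-size",
    "overlay-export",
    "log-level",
}


def parse_config_file(path: str | Path) -> dict[str, str]:
    """Parse a plain-text ``key = value`` config file (# comments allowed)."""
    values: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InputFormatError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        key = key.replace("_", "-")
        if key not in _CONFIG_KEYS:
            raise InputFormatError(f"{path}:{lineno}: unknown config key {key!r}")
        values[key] = value
    return values


def config_summary(config: RunConfig) -> str:
    p = dataclasses.asdict(config.params)
    param_text = ", ".join(f"{k}={v}" for k, v in p.items())
    return (
        f"input={config.input_path} output={config.output_dir} "
        f"link_3d={config.link_3d} voxel_size={config.voxel_size} | {param_text}"
    )
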