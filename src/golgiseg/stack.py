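"""In-memory container for grayscale image stacks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import InputFormatError

_DTYPE_BITS = {np.dtype(np.uint8): 8, np.dtype(np.uint16): 16}


@dataclass(frozen=True)
class ImageStack:
    """An ordered stack of same-shaped 8- or 16-bit grayscale slices.

    ``data`` has shape ``(slices, height, width)`` with dtype uint8 or
    uint16; a single image is a one-slice stack.  This is the unit of input
    and output for the whole pipeline.
    """

    data: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim == 2:
            arr = arr[np.newaxis, ...]
        if arr.ndim != 3:
            raise InputFormatError(f"stack must be 2D or 3D grayscale, got ndim={arr.ndim}")
        if arr.dtype not in _DTYPE_BITS:
            raise InputFormatError(
                f"stack dtype must be uint8 or uint16 (8/16-bit grayscale), got {arr.dtype}"
            )
        if arr.shape[0] < 1 or arr.shape[1] < 1 or arr.shape[2] < 1:
            raise InputFormatError(f"stack has empty dimension: shape {arr.shape}")
        object.__setattr__(self, "data", arr)

    @property
    def bit_depth(self) -> int:
        return _DTYPE_BITS[self.data.dtype]

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def __len__(self) -> int:
        return self.n_slices

    def __getitem__(self, i: int) -> np.ndarray:
        """Slice ``i`` (0-based) as a 2D array."""
        return self.data[i]
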