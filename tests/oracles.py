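"""Independent brute-force oracles for the raster and volume operations.

Everything here works directly from the set-theoretic definitions (explicit
offset enumeration, breadth-first flood fill) and never calls the library
code paths it is used to check.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def disc_offsets(radius: int) -> list[tuple[int, int]]:
    return [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]


def _shift(mask: np.ndarray, dy: int, dx: int, fill: bool) -> np.ndarray:
    """mask translated by (dy, dx); vacated cells take ``fill``."""
    out = np.full_like(mask, fill)
    h, w = mask.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = mask[ys_src, xs_src]
    return out


def dilate_oracle(mask: np.ndarray, radius: int) -> np.ndarray:
    """out[p] = any(mask[p - o] for o in disc); out-of-frame = background."""
    out = np.zeros_like(mask, dtype=bool)
    for dy, dx in disc_offsets(radius):
        out |= _shift(mask.astype(bool), dy, dx, fill=False)
    return out


def erode_oracle(mask: np.ndarray, radius: int) -> np.ndarray:
    """out[p] = all(mask[p + o] for o in disc); out-of-frame = foreground."""
    out = np.ones_like(mask, dtype=bool)
    for dy, dx in disc_offsets(radius):
        out &= _shift(mask.astype(bool), -dy, -dx, fill=True)
    return out


def close_oracle(mask: np.ndarray, radius: int) -> np.ndarray:
    return erode_oracle(dilate_oracle(mask, radius), radius)


def flood_fill_labels_2d(mask: np.ndarray) -> np.ndarray:
    """8-connected labeling by BFS, labels 1..n in raster-scan discovery order."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int64)
    h, w = mask.shape
    nxt = 0
    for y0 in range(h):
        for x0 in range(w):
            if not mask[y0, x0] or labels[y0, x0]:
                continue
            nxt += 1
            queue = deque([(y0, x0)])
            labels[y0, x0] = nxt
            while queue:
                y, x = queue.popleft()
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx_ = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx_ < w and mask[ny, nx_] and not labels[ny, nx_]:
                            labels[ny, nx_] = nxt
                            queue.append((ny, nx_))
    return labels


def flood_fill_labels_3d(volume: np.ndarray) -> np.ndarray:
    """26-connected labeling by BFS, labels in scan discovery order."""
    vol = np.asarray(volume, dtype=bool)
    labels = np.zeros(vol.shape, dtype=np.int64)
    nz, ny, nx = vol.shape
    neighbors = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    nxt = 0
    for z0 in range(nz):
        for y0 in range(ny):
            for x0 in range(nx):
                if not vol[z0, y0, x0] or labels[z0, y0, x0]:
                    continue
                nxt += 1
                queue = deque([(z0, y0, x0)])
                labels[z0, y0, x0] = nxt
                while queue:
                    z, y, x = queue.popleft()
                    for dz, dy, dx in neighbors:
                        p = (z + dz, y + dy, x + dx)
                        if (
                            0 <= p[0] < nz and 0 <= p[1] < ny and 0 <= p[2] < nx
                            and vol[p] and not labels[p]
                        ):
                            labels[p] = nxt
                            queue.append(p)
    return labels


def same_partition(labels_a: np.ndarray, labels_b: np.ndarray) -> bool:
    """True iff two label images induce the same foreground partition."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or not np.array_equal(a > 0, b > 0):
        return False
    fg = a > 0
    pairs = set(zip(a[fg].tolist(), b[fg].tolist()))
    # bijection between label sets
    return len(pairs) == len({p[0] for p in pairs}) == len({p[1] for p in pairs})
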