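"""Slide downsampling, patch tiling and the overlapping-offset lattice.

Slides are tiled into non-overlapping 224x224 patches on a grid; each grid
location is then expanded into a (2n+1)^2 lattice of overlapping patches by
stepping the top-left corner ``step`` pixels up to ``n_steps`` times in both
axes (defaults 20 px, 10 steps -> 441 candidates per interior patch).
Coordinates are 0-based (x = column, y = row) with half-open windows
[x, x+size) x [y, y+size) in downsampled slide space.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import downscale_local_mean

PATCH_SIZE = 224


@dataclass(frozen=True)
class PatchRef:
    """A square window located by its top-left pixel in slide space."""

    mouse_id: str
    x: int
    y: int
    size: int = PATCH_SIZE
    origin: str = "grid"  # grid | offset

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0 or self.size < 1:
            raise ValueError(f"invalid patch ref ({self.x}, {self.y}, {self.size})")
        if self.origin not in ("grid", "offset"):
            raise ValueError(f"origin must be 'grid' or 'offset', got {self.origin!r}")

    def in_bounds(self, height: int, width: int) -> bool:
        return self.x + self.size <= width and self.y + self.size <= height

    def window(self, image: np.ndarray) -> np.ndarray:
        return image[self.y:self.y + self.size, self.x:self.x + self.size]


@dataclass(frozen=True)
class OffsetLattice:
    """Offset expansion parameters: ``(2*n_steps+1)**2`` candidate positions."""

    step: int = 20
    n_steps: int = 10

    def __post_init__(self) -> None:
        if self.step < 1 or self.n_steps < 0:
            raise ValueError("step must be >= 1 and n_steps >= 0")

    @property
    def n_candidates(self) -> int:
        return (2 * self.n_steps + 1) ** 2


def downsample(image: np.ndarray, factor: int = 8) -> np.ndarray:
    """Area-average downsampling by an integer factor."""
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    if factor == 1:
        return image.copy()
    if min(image.shape[:2]) < factor:
        raise ValueError("image dimensions must be >= factor")
    h, w = (image.shape[0] // factor) * factor, (image.shape[1] // factor) * factor
    cropped = image[:h, :w]
    factors = (factor, factor) + (1,) * (image.ndim - 2)
    out = downscale_local_mean(cropped.astype(np.float64), factors)
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.rint(out), 0, 255).astype(image.dtype)
    return out.astype(image.dtype)


def tile_grid(dims: tuple[int, int], size: int = PATCH_SIZE,
              mouse_id: str = "") -> list[PatchRef]:
    """Non-overlapping grid tiling at stride = size, row-major; partial
    border tiles are discarded.  ``dims`` is (height, width)."""
    h, w = dims
    refs = []
    for y in range(0, h - size + 1, size):
        for x in range(0, w - size + 1, size):
            refs.append(PatchRef(mouse_id, x, y, size, "grid"))
    return refs


def expand_offsets(ref: PatchRef, lattice: OffsetLattice,
                   dims: tuple[int, int]) -> list[PatchRef]:
    """All in-bounds lattice offsets of ``ref`` (the original included once)."""
    h, w = dims
    if not ref.in_bounds(h, w):
        raise ValueError(f"ref {ref} out of bounds for dims {dims}")
    refs = []
    rng = range(-lattice.n_steps, lattice.n_steps + 1)
    for j in rng:
        for i in rng:
            x, y = ref.x + i * lattice.step, ref.y + j * lattice.step
            if x < 0 or y < 0 or x + ref.size > w or y + ref.size > h:
                continue
            if i == 0 and j == 0:
                refs.append(ref)
            else:
                refs.append(PatchRef(ref.mouse_id, x, y, ref.size, "offset"))
    return refs


def refs_to_manifest(refs: list[PatchRef]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.mouse_id, r.x, r.y, r.size, r.origin) for r in refs],
        columns=["mouse_id", "x", "y", "size", "origin"],
    )


def manifest_to_refs(manifest: pd.DataFrame) -> list[PatchRef]:
    return [PatchRef(str(r.mouse_id), int(r.x), int(r.y), int(r.size), str(r.origin))
            for r in manifest.itertuples()]


def write_manifest(refs: list[PatchRef], path: str | Path) -> None:
    refs_to_manifest(refs).to_csv(path, index=False)


def read_manifest(path: str | Path) -> list[PatchRef]:
    return manifest_to_refs(pd.read_csv(path))
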