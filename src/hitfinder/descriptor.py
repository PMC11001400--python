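"""Region-count image descriptor.

The classifier does not consume raw frames or peak positions; it consumes a
fixed-length vector of per-region key-point counts.  The frame is tiled by
a rectangular grid (default 2 rows x 4 columns, n = 8 regions, chosen for a
roughly symmetric coverage of the detector) and the number of detected key
points falling in each tile is tallied.  Miss frames, which carry no key
points, map to the all-zero vector, so the feature dimensionality is
constant across a data set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .detector import KeyPoint

__all__ = ["DescriptorParams", "DescriptorVector", "region_index", "compute_descriptor"]


@dataclass(frozen=True)
class DescriptorParams:
    """Grid tiling of the frame: ``grid_rows * grid_cols`` regions."""

    grid_rows: int = 2
    grid_cols: int = 4

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be >= 1")

    @property
    def n_regions(self) -> int:
        return self.grid_rows * self.grid_cols


@dataclass(frozen=True)
class DescriptorVector:
    """Per-region key-point counts for one frame."""

    counts: np.ndarray
    frame_shape: Tuple[int, int]

    def __len__(self) -> int:
        return len(self.counts)


def _tile_bounds(extent: int, n_tiles: int) -> np.ndarray:
    # tile t spans [floor(t*extent/n), floor((t+1)*extent/n)), half-open
    return np.array([t * extent // n_tiles for t in range(n_tiles + 1)])


def region_index(
    row: int,
    col: int,
    frame_shape: Tuple[int, int],
    params: DescriptorParams | None = None,
) -> int:
    """Region id of a pixel: row-major over the grid tiles.

    Tile boundaries are integer splits, half-open on the right, so every
    pixel belongs to exactly one region.
    """
    params = params or DescriptorParams()
    h, w = frame_shape
    if params.grid_rows > h or params.grid_cols > w:
        raise ValueError("grid dimensions exceed the frame dimensions")
    if not (0 <= row < h and 0 <= col < w):
        raise IndexError(f"({row}, {col}) outside frame {h}x{w}")
    tile_row = int(
        np.searchsorted(_tile_bounds(h, params.grid_rows), row, side="right") - 1
    )
    tile_col = int(
        np.searchsorted(_tile_bounds(w, params.grid_cols), col, side="right") - 1
    )
    return tile_row * params.grid_cols + tile_col


def compute_descriptor(
    keypoints: Sequence[KeyPoint],
    frame_shape: Tuple[int, int],
    params: DescriptorParams | None = None,
) -> DescriptorVector:
    """Tally key points per region; counts always sum to len(keypoints)."""
    params = params or DescriptorParams()
    counts = np.zeros(params.n_regions, dtype=np.int64)
    for kp in keypoints:
        counts[region_index(kp.row, kp.col, frame_shape, params)] += 1
    return DescriptorVector(counts=counts, frame_shape=tuple(frame_shape))


def descriptor_matrix(
    keypoint_lists: Iterable[Sequence[KeyPoint]],
    frame_shape: Tuple[int, int],
    params: DescriptorParams | None = None,
) -> np.ndarray:
    """Stack descriptors for many frames into an (N, n_regions) matrix."""
    params = params or DescriptorParams()
    rows: List[np.ndarray] = [
        compute_descriptor(kps, frame_shape, params).counts
        for kps in keypoint_lists
    ]
    if not rows:
        return np.empty((0, params.n_regions), dtype=np.int64)
    return np.stack(rows)
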