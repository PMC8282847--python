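"""Cube chunking: planning, extraction and overlap-averaged reassembly.

The network processes fixed-size cubes (64 voxels by default).  For
inference a map is covered by an overlapping grid of cubes with a small
stride (16 voxels); predictions are blended back by averaging every voxel
over all cubes that cover it.  For training a sparser grid is used.

Per axis of (padded) length N the cube origins are ``0, s, 2s, ...`` capped
at ``N - c``, with the final origin clamped to exactly ``N - c`` so the grid
always covers the full volume; the 3D grid is the Cartesian product of the
per-axis origin lists.  Maps smaller than the cube on any axis are padded
(with the map's noise mean, i.e. ~0 after normalization) and the padding is
cropped again on reassembly.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

__all__ = ["ChunkGrid", "plan_chunks", "extract_chunks", "assemble_chunks", "coverage_counts"]


@dataclasses.dataclass(frozen=True)
class ChunkGrid:
    """Deterministic plan of cube origins covering a (padded) volume."""

    cube_size: int
    stride: int
    origins: tuple[tuple[int, int, int], ...]
    padded_shape: tuple[int, int, int]
    pad_value: float = 0.0

    def __post_init__(self) -> None:
        for o in self.origins:
            if any(v < 0 or v + self.cube_size > n for v, n in zip(o, self.padded_shape)):
                raise ValueError(f"origin {o} outside padded shape {self.padded_shape}")

    def __len__(self) -> int:
        return len(self.origins)


def _axis_origins(n: int, cube: int, stride: int) -> list[int]:
    last = n - cube
    origins = list(range(0, last + 1, stride))
    if origins[-1] != last:
        origins.append(last)
    return origins


def plan_chunks(
    shape: tuple[int, int, int],
    cube_size: int = 64,
    stride: int = 16,
    pad_value: float = 0.0,
) -> ChunkGrid:
    """Plan a covering grid of ``cube_size`` cubes at the given stride."""
    if cube_size < 1:
        raise ValueError(f"cube_size must be >= 1, got {cube_size}")
    if not 1 <= stride <= cube_size:
        raise ValueError(f"stride must be in [1, cube_size], got {stride}")
    padded = tuple(max(int(n), cube_size) for n in shape)
    per_axis = [_axis_origins(n, cube_size, stride) for n in padded]
    origins = tuple(itertools.product(*per_axis))  # lexicographically sorted
    return ChunkGrid(cube_size, stride, origins, padded, float(pad_value))


def _pad_to(data: np.ndarray, padded_shape: tuple[int, int, int], value: float) -> np.ndarray:
    if tuple(data.shape) == tuple(padded_shape):
        return data
    pads = [(0, p - n) for n, p in zip(data.shape, padded_shape)]
    return np.pad(data, pads, mode="constant", constant_values=value)


def extract_chunks(data: np.ndarray, grid: ChunkGrid) -> np.ndarray:
    """Extract all cubes of ``grid`` from ``data`` (origin order), padding
    undersized volumes with ``grid.pad_value``."""
    if any(n > p for n, p in zip(data.shape, grid.padded_shape)):
        raise ValueError(f"data shape {data.shape} exceeds padded shape {grid.padded_shape}")
    padded = _pad_to(np.asarray(data), grid.padded_shape, grid.pad_value)
    c = grid.cube_size
    out = np.empty((len(grid), c, c, c), dtype=padded.dtype)
    for i, (z, y, x) in enumerate(grid.origins):
        out[i] = padded[z : z + c, y : y + c, x : x + c]
    return out


def assemble_chunks(
    cubes: np.ndarray, grid: ChunkGrid, out_shape: tuple[int, int, int]
) -> np.ndarray:
    """Reassemble cubes into a volume, averaging overlapping regions."""
    cubes = np.asarray(cubes)
    if len(cubes) != len(grid):
        raise ValueError(f"{len(cubes)} cubes for {len(grid)} origins")
    c = grid.cube_size
    acc = np.zeros(grid.padded_shape, dtype=np.float64)
    cnt = np.zeros(grid.padded_shape, dtype=np.int32)
    for cube, (z, y, x) in zip(cubes, grid.origins):
        acc[z : z + c, y : y + c, x : x + c] += cube
        cnt[z : z + c, y : y + c, x : x + c] += 1
    assert cnt.min() >= 1, "chunk grid left voxels uncovered"
    acc /= cnt
    sl = tuple(slice(0, n) for n in out_shape)
    return acc[sl].astype(np.float32)


def coverage_counts(grid: ChunkGrid) -> np.ndarray:
    """How many cubes cover each voxel of the padded volume."""
    c = grid.cube_size
    cnt = np.zeros(grid.padded_shape, dtype=np.int32)
    for z, y, x in grid.origins:
        cnt[z : z + c, y : y + c, x : x + c] += 1
    return cnt
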