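"""Reading, writing and resampling of cryo-EM density maps.

Maps are carried through the pipeline as :class:`DensityMap` objects: a 3D
float32 grid in canonical ``(z, y, x)`` axis order together with an isotropic
voxel size in Angstrom and a physical origin.  Files on disk are MRC2014 /
CCP4 volumes, parsed and emitted through :mod:`gemmi`.

The pipeline operates internally on a fixed 1 Angstrom/voxel working grid so
that molecular features always span the same number of voxels regardless of
how a map was deposited.  :func:`resample_to_working_grid` moves a map onto
that grid and :func:`resize_to_original` moves results back; both use a
Fourier-space resize (zero-pad / crop of the centred spectrum), which is
exactly band-limited and linear.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Sequence

import numpy as np
import scipy.fft

__all__ = [
    "DensityMap",
    "ResampleRecord",
    "read_map",
    "write_map",
    "average_half_maps",
    "resample_to_working_grid",
    "resize_to_original",
    "fourier_resize",
]

#: MRC data modes holding real scalar values (int8, int16, float32, float16).
_REAL_MODES = (0, 1, 2, 12)

WORKING_VOXEL_SIZE = 1.0


@dataclasses.dataclass
class DensityMap:
    """A 3D scalar density grid with physical metadata.

    Attributes
    ----------
    data:
        3D array indexed ``(z, y, x)``; stored as float32.
    voxel_size:
        Isotropic sampling in Angstrom per voxel.
    origin:
        Physical position (x, y, z, Angstrom) of grid index ``(0, 0, 0)``.
    """

    data: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"density grid must be 3D, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"degenerate grid shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("density grid contains NaN/Inf values")
        self.voxel_size = float(self.voxel_size)
        if not self.voxel_size > 0:
            raise ValueError(f"voxel size must be positive, got {self.voxel_size}")
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    def with_data(self, data: np.ndarray) -> "DensityMap":
        """New map sharing this map's metadata but holding ``data``."""
        return DensityMap(data, self.voxel_size, self.origin)


@dataclasses.dataclass(frozen=True)
class ResampleRecord:
    """Everything needed to undo a resampling onto the working grid."""

    original_shape: tuple[int, int, int]
    original_voxel_size: float
    original_origin: tuple[float, float, float]
    working_voxel_size: float = WORKING_VOXEL_SIZE

    def __post_init__(self) -> None:
        if not self.original_voxel_size > 0 or not self.working_voxel_size > 0:
            raise ValueError("voxel sizes must be positive")
        if any(s < 1 for s in self.original_shape):
            raise ValueError(f"degenerate original shape {self.original_shape}")


def read_map(path: str | os.PathLike, *, allow_anisotropic: bool = False) -> DensityMap:
    """Read an MRC/CCP4 map into canonical ``(z, y, x)`` order.

    The axis permutation recorded in MAPC/MAPR/MAPS is normalised, so two
    files storing the same volume under different axis conventions read back
    identically.  The voxel size comes from the cell dimensions divided by
    the grid sampling; the origin from the ORIGIN record, falling back to
    NXSTART times the voxel size.

    Parameters
    ----------
    allow_anisotropic:
        Accept maps whose per-axis voxel sizes differ by more than 1%
        (the mean spacing is then reported as ``voxel_size``).
    """
    import gemmi

    if not os.path.exists(path):
        raise FileNotFoundError(f"map file not found: {path}")
    ccp4 = gemmi.read_ccp4_map(str(path))
    mode = ccp4.header_i32(4)
    if mode not in _REAL_MODES:
        raise ValueError(f"MRC mode {mode} is not a real-valued volume mode")
    origin = tuple(ccp4.header_float(i) for i in (50, 51, 52))
    nstart = tuple(ccp4.header_i32(i) for i in (5, 6, 7))
    # Normalise any MAPC/MAPR/MAPS axis permutation without resizing the grid.
    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    spacing = np.array(ccp4.grid.spacing, dtype=float)  # (dx, dy, dz)
    if np.any(spacing <= 0):
        raise ValueError(f"non-positive voxel size in header: {spacing}")
    rel_spread = (spacing.max() - spacing.min()) / spacing.mean()
    if rel_spread > 0.01 and not allow_anisotropic:
        raise ValueError(
            f"anisotropic voxel size {spacing} (spread {rel_spread:.1%}); "
            "pass allow_anisotropic=True to accept"
        )
    voxel = float(spacing.mean())
    if all(abs(v) < 1e-6 for v in origin) and any(nstart):
        origin = tuple(n * voxel for n in nstart)
    data = np.asarray(ccp4.grid, dtype=np.float32).T  # (x,y,z) -> (z,y,x)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"map {path} contains non-finite values")
    return DensityMap(np.ascontiguousarray(data), voxel, origin)


def write_map(dmap: DensityMap, path: str | os.PathLike) -> None:
    """Write ``dmap`` as an MRC2014 file (mode 2, float32, P1 cell)."""
    import gemmi

    nz, ny, nx = dmap.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    np.asarray(grid)[...] = dmap.data.T  # canonical (z,y,x) -> gemmi (x,y,z)
    grid.unit_cell = gemmi.UnitCell(
        nx * dmap.voxel_size, ny * dmap.voxel_size, nz * dmap.voxel_size, 90, 90, 90
    )
    grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for i, v in zip((50, 51, 52), dmap.origin):
        ccp4.set_header_float(i, float(v))
    ccp4.write_ccp4_map(str(path))


def average_half_maps(half1: DensityMap, half2: DensityMap) -> DensityMap:
    """Voxel-wise mean of two half maps (metadata taken from ``half1``).

    Averaging the two independent half reconstructions yields the full map
    and halves the noise variance while leaving the signal untouched.
    """
    if half1.shape != half2.shape:
        raise ValueError(f"half map shapes differ: {half1.shape} vs {half2.shape}")
    rel = abs(half1.voxel_size - half2.voxel_size) / half1.voxel_size
    if rel > 1e-4:
        raise ValueError(
            f"half map voxel sizes differ: {half1.voxel_size} vs {half2.voxel_size}"
        )
    return half1.with_data(0.5 * (half1.data + half2.data))


def _centered_slice_pair(n_in: int, n_out: int) -> tuple[slice, slice]:
    """Slices aligning the DC-centred spectra of lengths n_in and n_out."""
    m = min(n_in, n_out)
    a = n_in // 2 - m // 2
    b = n_out // 2 - m // 2
    return slice(a, a + m), slice(b, b + m)


def fourier_resize(data: np.ndarray, out_shape: Sequence[int]) -> np.ndarray:
    """Resize a real 3D array by zero-padding/cropping its centred DFT.

    Exactly band-limited and linear; values are rescaled so that a constant
    array keeps its value at any output size.
    """
    out_shape = tuple(int(s) for s in out_shape)
    if tuple(data.shape) == out_shape:
        return np.asarray(data, dtype=np.float32).copy()
    spec = scipy.fft.fftshift(scipy.fft.fftn(np.asarray(data, dtype=np.float64)))
    out = np.zeros(out_shape, dtype=complex)
    src, dst = zip(*(_centered_slice_pair(i, o) for i, o in zip(data.shape, out_shape)))
    out[tuple(dst)] = spec[tuple(src)]
    scale = np.prod(out_shape) / np.prod(data.shape)
    res = scipy.fft.ifftn(scipy.fft.ifftshift(out)).real * scale
    return res.astype(np.float32)


def _spline_resize(data: np.ndarray, out_shape: Sequence[int]) -> np.ndarray:
    import scipy.ndimage

    zoom = [o / i for o, i in zip(out_shape, data.shape)]
    return scipy.ndimage.zoom(
        np.asarray(data, dtype=np.float64), zoom, order=3, grid_mode=True, mode="grid-constant"
    ).astype(np.float32)


def resample_to_working_grid(
    dmap: DensityMap,
    target_voxel: float = WORKING_VOXEL_SIZE,
    *,
    method: str = "fourier",
) -> tuple[DensityMap, ResampleRecord]:
    """Resample a map to ``target_voxel`` Angstrom/voxel.

    Output shape per axis is ``round(n * voxel_size / target_voxel)`` with
    round-half-away-from-zero.  ``method`` is ``"fourier"`` (default,
    band-limited) or ``"spline"`` (real-space cubic spline).
    """
    if not target_voxel > 0:
        raise ValueError("target voxel size must be positive")
    record = ResampleRecord(dmap.shape, dmap.voxel_size, dmap.origin, target_voxel)
    ratio = dmap.voxel_size / target_voxel
    out_shape = tuple(int(np.floor(n * ratio + 0.5)) for n in dmap.shape)
    if any(s < 4 for s in out_shape):
        raise ValueError(f"resampled shape {out_shape} is degenerate (< 4 voxels)")
    if abs(ratio - 1.0) < 1e-9:
        return DensityMap(dmap.data.copy(), target_voxel, dmap.origin), record
    if method == "fourier":
        data = fourier_resize(dmap.data, out_shape)
    elif method == "spline":
        data = _spline_resize(dmap.data, out_shape)
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    return DensityMap(data, target_voxel, dmap.origin), record


def resize_to_original(
    dmap: DensityMap, record: ResampleRecord, *, method: str = "fourier"
) -> DensityMap:
    """Resize a working-grid map back onto the grid described by ``record``."""
    if any(s < 1 for s in record.original_shape):
        raise ValueError(f"inconsistent record: shape {record.original_shape}")
    if method == "fourier":
        data = fourier_resize(dmap.data, record.original_shape)
    elif method == "spline":
        data = _spline_resize(dmap.data, record.original_shape)
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    return DensityMap(data, record.original_voxel_size, record.original_origin)
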