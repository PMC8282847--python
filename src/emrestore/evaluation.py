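"""Map-similarity metrics: FSC curves, threshold resolutions, correlations.

The Fourier shell correlation (FSC) between maps A and B is, per spherical
shell of spatial frequency,

    FSC(s) = Re{ sum F_A conj(F_B) } / sqrt( sum |F_A|^2 * sum |F_B|^2 ),

with shells one Fourier voxel wide (anisotropic boxes use the per-axis
normalized frequency norm).  Resolution is reported at the first crossing
of a threshold (0.5 when comparing against an external reference map),
linearly interpolated in frequency; curves that never fall below the
threshold report the Nyquist resolution 2 * voxel_size with a flag.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.fft
import scipy.ndimage

from .synthetic_data import MaskVolume
from .volume_io import DensityMap

__all__ = [
    "FSCCurve",
    "Resolution",
    "fsc",
    "resolution_at_threshold",
    "soften_mask",
    "masked_fsc",
    "real_space_cc",
    "evaluate_run",
]


@dataclasses.dataclass(frozen=True)
class FSCCurve:
    """Per-shell correlation with its frequency axis (1/Angstrom)."""

    shell_freq: np.ndarray  # shell centers, 1/Angstrom; shell 0 is DC
    fsc: np.ndarray
    n_voxels: np.ndarray  # Fourier voxels per shell
    voxel_size: float

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.shell_freq) > 0):
            raise ValueError("shell frequencies must be strictly increasing")
        nyq = 1.0 / (2.0 * self.voxel_size)
        if self.shell_freq.max() > nyq * (1 + 1e-9):
            raise ValueError("shell frequency above Nyquist")
        if not np.all(np.isfinite(self.fsc)) or np.any(np.abs(self.fsc) > 1 + 1e-9):
            raise ValueError("FSC values must be finite and within [-1, 1]")
        if np.any(self.n_voxels < 1):
            raise ValueError("each shell must contain at least one Fourier voxel")


class Resolution(float):
    """Resolution in Angstrom with flags describing threshold-search corner
    cases (float subclass, so it compares like a plain number)."""

    reached_nyquist: bool = False
    below_from_start: bool = False

    def __new__(cls, value, reached_nyquist=False, below_from_start=False):
        obj = super().__new__(cls, value)
        obj.reached_nyquist = reached_nyquist
        obj.below_from_start = below_from_start
        return obj


def _shell_index(shape: tuple[int, int, int]) -> tuple[np.ndarray, int]:
    """Integer shell index per Fourier voxel, normalized per axis so the
    Nyquist of every axis lands on the same shell."""
    n_shells = min(shape) // 2 + 1
    axes = [np.abs(scipy.fft.fftfreq(n)) * 2 * (n_shells - 1) for n in shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)
    radius = np.sqrt(zz**2 + yy**2 + xx**2)
    return np.rint(radius).astype(np.int64), n_shells


def fsc(map1: DensityMap, map2: DensityMap) -> FSCCurve:
    """Fourier shell correlation between two maps on the same grid."""
    if map1.shape != map2.shape:
        raise ValueError(f"shape mismatch: {map1.shape} vs {map2.shape}")
    if abs(map1.voxel_size - map2.voxel_size) > 1e-6 * map1.voxel_size:
        raise ValueError("voxel size mismatch")
    a = np.asarray(map1.data, dtype=np.float64)
    b = np.asarray(map2.data, dtype=np.float64)
    if not a.any() or not b.any():
        raise ValueError("FSC undefined for an all-zero map")
    fa = scipy.fft.fftn(a)
    fb = scipy.fft.fftn(b)
    shell, n_shells = _shell_index(map1.shape)
    flat = shell.ravel()
    keep = flat < n_shells  # drop corner voxels beyond the Nyquist sphere
    flat = flat[keep]
    cross = np.bincount(flat, (fa * np.conj(fb)).real.ravel()[keep], minlength=n_shells)
    p1 = np.bincount(flat, (np.abs(fa) ** 2).ravel()[keep], minlength=n_shells)
    p2 = np.bincount(flat, (np.abs(fb) ** 2).ravel()[keep], minlength=n_shells)
    counts = np.bincount(flat, minlength=n_shells)
    denom = np.sqrt(p1 * p2)
    vals = np.divide(cross, denom, out=np.zeros(n_shells), where=denom > 0)
    nyquist = 1.0 / (2.0 * map1.voxel_size)
    freqs = np.arange(n_shells) * nyquist / (n_shells - 1)
    return FSCCurve(freqs, np.clip(vals, -1.0, 1.0), counts, map1.voxel_size)


def resolution_at_threshold(curve: FSCCurve, threshold: float = 0.5) -> Resolution:
    """Resolution (Angstrom) at the first threshold crossing of the curve.

    The DC shell is excluded from the search.  Linear interpolation between
    the shells straddling the crossing; never-crossing curves return the
    Nyquist resolution flagged ``reached_nyquist``; curves already below the
    threshold at the first usable shell return inf flagged
    ``below_from_start``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    f = curve.fsc
    if len(f) < 3:
        raise ValueError("curve too short")
    if f[1] < threshold:
        return Resolution(np.inf, below_from_start=True)
    for k in range(1, len(f) - 1):
        if f[k] >= threshold > f[k + 1]:
            f0, f1 = f[k], f[k + 1]
            s0, s1 = curve.shell_freq[k], curve.shell_freq[k + 1]
            s = s0 + (f0 - threshold) / (f0 - f1) * (s1 - s0)
            return Resolution(1.0 / s)
    return Resolution(2.0 * curve.voxel_size, reached_nyquist=True)


def soften_mask(mask: MaskVolume, width: float) -> np.ndarray:
    """Cosine-edge softened mask: 1 inside, falling to 0 over ``width``
    voxels outside the binary support (``width`` = 0 keeps it hard)."""
    hard = mask.bool_data
    if width <= 0:
        return hard.astype(np.float64)
    dist = scipy.ndimage.distance_transform_edt(~hard)
    soft = np.zeros(hard.shape)
    soft[hard] = 1.0
    edge = (dist > 0) & (dist <= width)
    soft[edge] = 0.5 * (1.0 + np.cos(np.pi * dist[edge] / width))
    return soft


def masked_fsc(
    map1: DensityMap, map2: DensityMap, mask: MaskVolume, soften_width: float = 3.0
) -> FSCCurve:
    """FSC after multiplying both maps with a cosine-softened mask."""
    soft = soften_mask(mask, soften_width)
    return fsc(map1.with_data(map1.data * soft), map2.with_data(map2.data * soft))


def real_space_cc(
    map1: DensityMap, map2: DensityMap, mask: MaskVolume | None = None
) -> float:
    """Pearson correlation of voxel intensities (optionally within a mask)."""
    if map1.shape != map2.shape:
        raise ValueError(f"shape mismatch: {map1.shape} vs {map2.shape}")
    a = map1.data.astype(np.float64).ravel()
    b = map2.data.astype(np.float64).ravel()
    if mask is not None:
        sel = mask.bool_data.ravel()
        a, b = a[sel], b[sel]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(np.corrcoef(a, b)[0, 1])


def evaluate_run(
    inputs: list[DensityMap],
    predictions: list[DensityMap],
    targets: list[DensityMap],
    masks: list[MaskVolume] | None = None,
    *,
    fsc_threshold: float = 0.5,
    soften_width: float = 3.0,
):
    """Per-map quality table comparing inputs and predictions to targets.

    Columns: real-space CC of input and prediction vs target, FSC threshold
    resolutions (plain and tight-masked) of both vs target.  Returns a
    pandas DataFrame; ``df.attrs['medians']`` carries the column medians.
    """
    import pandas as pd

    if not len(inputs) == len(predictions) == len(targets):
        raise ValueError("inputs, predictions and targets must be aligned")
    if masks is not None and len(masks) != len(inputs):
        raise ValueError("masks must align with maps")
    rows = []
    for i, (inp, pred, tgt) in enumerate(zip(inputs, predictions, targets)):
        row = {
            "map_id": f"map_{i:03d}",
            "cc_input": real_space_cc(inp, tgt),
            "cc_pred": real_space_cc(pred, tgt),
            "res_input_A": float(resolution_at_threshold(fsc(inp, tgt), fsc_threshold)),
            "res_pred_A": float(resolution_at_threshold(fsc(pred, tgt), fsc_threshold)),
        }
        if masks is not None:
            m = masks[i]
            row["res_input_masked_A"] = float(
                resolution_at_threshold(masked_fsc(inp, tgt, m, soften_width), fsc_threshold)
            )
            row["res_pred_masked_A"] = float(
                resolution_at_threshold(masked_fsc(pred, tgt, m, soften_width), fsc_threshold)
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["medians"] = df.drop(columns="map_id").median().to_dict()
    return df
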