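"""Noise-statistics intensity normalization.

Experimental maps arrive on arbitrary intensity scales.  Following the
classical cryo-EM convention, each map is linearly rescaled so that its
*noise* (solvent) region has mean 0 and standard deviation 0.1.  The noise
region is taken from an explicit mask when one is supplied; otherwise a
geometric heuristic is used: the particle in a deposited map is centred and
boxed with margin, so voxels that lie outside the largest centred sphere
*and* near the box faces are overwhelmingly solvent.

Masked target maps have no noise region at all (solvent is exactly zero), so
they are instead scaled so that the 95th percentile of in-mask intensity
equals 1.0 (:func:`normalize_target`), giving all training targets a common
scale.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .volume_io import DensityMap

__all__ = [
    "NormalizationStats",
    "noise_region_mask",
    "estimate_noise_stats",
    "normalize",
    "denormalize",
    "normalize_target",
]

TARGET_NOISE_MEAN = 0.0
TARGET_NOISE_STD = 0.1

#: Exclude the centred sphere of radius 0.9 * (min dim)/2 ...
_SPHERE_RADIUS_FRACTION = 0.9
#: ... and keep only voxels within this fraction of a box face.
_SHELL_FRACTION = 0.15
#: Robustness: drop noise voxels beyond this many MADs from the median.
_MAD_CUTOFF = 4.0


@dataclasses.dataclass(frozen=True)
class NormalizationStats:
    """Linear transform mapping raw intensities to the normalized scale."""

    noise_mean: float
    noise_std: float
    target_mean: float = TARGET_NOISE_MEAN
    target_std: float = TARGET_NOISE_STD
    noise_region: str = "outer-shell"

    def __post_init__(self) -> None:
        if not self.noise_std > 0:
            raise ValueError(f"noise std must be positive, got {self.noise_std}")
        if not self.target_std > 0:
            raise ValueError(f"target std must be positive, got {self.target_std}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def noise_region_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Boolean mask of the default solvent/noise region of a box.

    Voxels outside the centred sphere of radius ``0.9 * min(shape)/2`` that
    also lie in the outer 15% shell of the box (within 15% of any face).
    """
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    center = [(n - 1) / 2.0 for n in shape]
    r2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    radius = _SPHERE_RADIUS_FRACTION * (min(shape) / 2.0)
    outside_sphere = r2 > radius**2
    near_face = np.zeros(shape, dtype=bool)
    for axis, n in enumerate(shape):
        edge = max(1, int(np.ceil(_SHELL_FRACTION * n)))
        idx = np.arange(n)
        band = (idx < edge) | (idx >= n - edge)
        shp = [1, 1, 1]
        shp[axis] = n
        near_face |= band.reshape(shp)
    return outside_sphere & near_face


def estimate_noise_stats(
    dmap: DensityMap, noise_mask: np.ndarray | None = None
) -> NormalizationStats:
    """Mean/std of the map over its noise region.

    An explicit boolean ``noise_mask`` overrides the default outer-shell
    heuristic.  The std is computed after discarding values beyond 4 MADs
    from the noise median, so stray signal in the shell does not inflate it.
    """
    if noise_mask is not None:
        mask = np.asarray(noise_mask).astype(bool)
        if mask.shape != dmap.shape:
            raise ValueError(f"noise mask shape {mask.shape} != map shape {dmap.shape}")
        region = "explicit-mask"
    else:
        mask = noise_region_mask(dmap.shape)
        region = "outer-shell"
    values = dmap.data[mask].astype(np.float64)
    if values.size == 0:
        raise ValueError("noise region is empty")
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad > 0:
        values = values[np.abs(values - med) <= _MAD_CUTOFF * mad * 1.4826]
    mean = float(values.mean())
    std = float(values.std())
    data_range = float(dmap.data.max() - dmap.data.min())
    if std <= 1e-12 * max(data_range, 1.0):
        raise ValueError("flat noise region: cannot estimate noise statistics")
    return NormalizationStats(mean, std, noise_region=region)


def normalize(dmap: DensityMap, stats: NormalizationStats) -> DensityMap:
    """Affine rescale so the noise region adopts (target_mean, target_std)."""
    scale = stats.target_std / stats.noise_std
    out = (dmap.data - stats.noise_mean) * scale + stats.target_mean
    return dmap.with_data(out)


def denormalize(dmap: DensityMap, stats: NormalizationStats) -> DensityMap:
    """Exact inverse of :func:`normalize`."""
    scale = stats.noise_std / stats.target_std
    out = (dmap.data - stats.target_mean) * scale + stats.noise_mean
    return dmap.with_data(out)


def normalize_target(dmap: DensityMap, mask: np.ndarray) -> DensityMap:
    """Scale a tightly masked target so its in-mask 95th percentile is 1.0.

    Solvent voxels of a masked target are exactly zero, so noise-statistics
    normalization is undefined there; a percentile-to-one rule gives every
    target the same intensity scale instead.
    """
    m = np.asarray(mask).astype(bool)
    if m.shape != dmap.shape:
        raise ValueError(f"mask shape {m.shape} != map shape {dmap.shape}")
    if not m.any():
        raise ValueError("empty mask: cannot normalize target")
    p95 = float(np.percentile(dmap.data[m], 95))
    if p95 <= 0:
        raise ValueError(f"non-positive in-mask 95th percentile ({p95})")
    return dmap.with_data(dmap.data / p95)
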