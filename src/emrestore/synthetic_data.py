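"""Synthetic map-pair generation for training and validating the pipeline.

Real training data for this method is a pair per deposited entry: an
unsharpened experimental map (average of two half maps) as input, and a
tightly masked, locally sharpened map as target.  This module generates
volumes with the same statistical structure, fully in silico:

1. a pseudo-atomic model — a self-avoiding random walk with 3.8 Angstrom
   steps (protein backbone C-alpha spacing) carrying per-atom amplitudes
   and B-factors;
2. a *sharp* reference map — a sum of isotropic Gaussians, one per atom,
   whose widths follow the atomic B-factors;
3. a *degraded* experimental-like map — the sharp map attenuated in Fourier
   space by exp(-B s^2 / 4) (crystallographic amplitude convention),
   optionally with a smoothly varying local B-factor field, plus
   independent noise in each of two half maps (the full map is their mean);
4. a *tight mask* — the sharp map thresholded at a fraction of its maximum
   and dilated by a small ball; and
5. the *target* — the sharp map multiplied by the mask.

What this emulates: band-limited molecule-like signal, global and spatially
varying contrast loss, independent half-map noise, tight solvent masking.
What it does not: electron scattering factors, CTF effects, reconstruction
artifacts, solvent/lipid densities.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.fft
import scipy.ndimage

from .volume_io import DensityMap

__all__ = [
    "PseudoModel",
    "DegradeSpec",
    "MaskVolume",
    "SyntheticSpec",
    "SyntheticMapPair",
    "random_pseudo_model",
    "simulate_sharp_map",
    "degrade_map",
    "make_mask",
    "make_target",
    "generate_dataset",
    "smooth_b_field",
]

#: Base Gaussian width (Angstrom) of a zero-B atom.
BASE_SIGMA = 0.8
#: Backbone-like step length between consecutive pseudo-atoms (Angstrom).
STEP_LENGTH = 3.8


@dataclasses.dataclass(frozen=True)
class PseudoModel:
    """Pseudo-atomic model: positions (Angstrom), amplitudes, B-factors."""

    positions: np.ndarray  # (n, 3) as (z, y, x) Angstrom
    amplitudes: np.ndarray  # (n,)
    b_factors: np.ndarray  # (n,) Angstrom^2
    box_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if np.any(self.amplitudes <= 0):
            raise ValueError("amplitudes must be positive")
        if np.any(self.b_factors < 0):
            raise ValueError("B-factors must be nonnegative")
        for ax in range(3):
            if np.any(self.positions[:, ax] < 0) or np.any(
                self.positions[:, ax] > self.box_size[ax]
            ):
                raise ValueError("atom positions outside box")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)


@dataclasses.dataclass(frozen=True)
class DegradeSpec:
    """Contrast-loss and noise parameters for one simulated map."""

    global_b: float = 100.0  # Angstrom^2
    noise_sigma: float = 0.0
    noise_type: str = "white"  # "white" | "bandlimited"
    local_b_amplitude: float = 0.0  # extra B at the high-B end of the field
    local_b_scale: float = 20.0  # correlation length (voxels) of the field
    seed: int = 0

    def __post_init__(self) -> None:
        if self.global_b < 0 or self.noise_sigma < 0 or self.local_b_amplitude < 0:
            raise ValueError("global_b, noise_sigma, local_b_amplitude must be >= 0")
        if self.noise_type not in ("white", "bandlimited"):
            raise ValueError(f"unknown noise type {self.noise_type!r}")


@dataclasses.dataclass(frozen=True)
class MaskVolume:
    """Binary or soft mask over a map grid, values in [0, 1]."""

    data: np.ndarray
    voxel_size: float
    binary: bool = True

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.min() < 0 or d.max() > 1:
            raise ValueError("mask values must lie in [0, 1]")
        if self.binary and not np.isin(d, (0, 1)).all():
            raise ValueError("binary mask contains non-{0,1} values")
        if not d.any():
            raise ValueError("mask has empty support")

    @property
    def bool_data(self) -> np.ndarray:
        return np.asarray(self.data) > 0.5


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Full parameter record of one generated map pair."""

    n_atoms: int
    grid_shape: tuple[int, int, int]
    voxel_size: float
    global_b: float
    noise_sigma: float
    peak_snr: float
    local_b_amplitude: float
    threshold_fraction: float
    dilation_radius: int
    seed: int


@dataclasses.dataclass
class SyntheticMapPair:
    """One generated training example (all maps share one grid)."""

    spec: SyntheticSpec
    sharp: DensityMap
    full: DensityMap
    half1: DensityMap
    half2: DensityMap
    mask: MaskVolume
    target: DensityMap


def random_pseudo_model(
    n_atoms: int,
    box_size: float | tuple[float, float, float],
    seed: int,
    *,
    amplitude_range: tuple[float, float] = (0.8, 1.2),
    b_range: tuple[float, float] = (5.0, 30.0),
    margin: float = 8.0,
    min_separation: float = 2.0,
) -> PseudoModel:
    """Self-avoiding random walk with 3.8 Angstrom steps inside the box."""
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    box = tuple(float(b) for b in (box_size,) * 3) if np.isscalar(box_size) else tuple(
        float(b) for b in box_size
    )
    if any(b <= 2 * margin for b in box):
        raise ValueError(f"box {box} too small for margin {margin}")
    rng = np.random.default_rng(seed)
    lo = np.full(3, margin)
    hi = np.array(box) - margin
    pos = [lo + (hi - lo) * (0.35 + 0.3 * rng.random(3))]
    attempts = 0
    while len(pos) < n_atoms:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        cand = pos[-1] + STEP_LENGTH * direction
        prev = np.array(pos[:-1]) if len(pos) > 1 else np.empty((0, 3))
        ok = np.all(cand >= lo) and np.all(cand <= hi)
        if ok and len(prev):
            ok = np.min(np.linalg.norm(prev - cand, axis=1)) >= min_separation
        if ok:
            pos.append(cand)
            attempts = 0
        else:
            attempts += 1
            if attempts > 200:  # stuck: restart the walk from a visited atom
                pos = pos[: max(1, len(pos) // 2)]
                attempts = 0
    positions = np.array(pos)
    return PseudoModel(
        positions=positions,
        amplitudes=rng.uniform(*amplitude_range, size=n_atoms),
        b_factors=rng.uniform(*b_range, size=n_atoms),
        box_size=box,
    )


def simulate_sharp_map(
    model: PseudoModel,
    voxel_size: float,
    grid_shape: tuple[int, int, int],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> DensityMap:
    """Sum of per-atom isotropic Gaussians evaluated on the grid.

    Atom width sigma^2 = B/(8 pi^2) + sigma_0^2 with sigma_0 = 0.8 Angstrom;
    each Gaussian peaks at the atom's amplitude.
    """
    data = np.zeros(grid_shape, dtype=np.float64)
    box_hi = [o + (n - 1) * voxel_size for o, n in zip(origin[::-1], grid_shape)]
    for p, a, b in zip(model.positions, model.amplitudes, model.b_factors):
        sigma = np.sqrt(b / (8 * np.pi**2) + BASE_SIGMA**2)
        if np.any(p < np.array(origin[::-1]) - 1e-9) or np.any(p > np.array(box_hi) + 1e-9):
            raise ValueError(f"atom at {p} outside grid")
        idx = (p - np.array(origin[::-1])) / voxel_size
        r = int(np.ceil(4 * sigma / voxel_size))
        lo = [max(0, int(np.floor(i)) - r) for i in idx]
        hi = [min(n, int(np.floor(i)) + r + 2) for i, n in zip(idx, grid_shape)]
        zz, yy, xx = np.meshgrid(
            *(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij"
        )
        d2 = ((zz - idx[0]) ** 2 + (yy - idx[1]) ** 2 + (xx - idx[2]) ** 2) * voxel_size**2
        data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += a * np.exp(-d2 / (2 * sigma**2))
    return DensityMap(data, voxel_size, origin)


def _freq_sq_grid(shape: tuple[int, int, int], voxel_size: float) -> np.ndarray:
    axes = [scipy.fft.fftfreq(n, d=voxel_size) for n in shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)
    return zz**2 + yy**2 + xx**2


def _attenuate(data: np.ndarray, b: float, voxel_size: float) -> np.ndarray:
    if b == 0:
        return np.asarray(data, dtype=np.float64)
    s2 = _freq_sq_grid(data.shape, voxel_size)
    spec = scipy.fft.fftn(np.asarray(data, dtype=np.float64))
    return scipy.fft.ifftn(spec * np.exp(-b * s2 / 4.0)).real


def smooth_b_field(
    shape: tuple[int, int, int], scale: float, seed: int
) -> np.ndarray:
    """Smooth random field in [0, 1] with correlation length ``scale`` voxels."""
    rng = np.random.default_rng(seed)
    field = scipy.ndimage.gaussian_filter(rng.normal(size=shape), scale)
    lo, hi = field.min(), field.max()
    return (field - lo) / (hi - lo) if hi > lo else np.full(shape, 0.5)


def _draw_noise(rng, shape, sigma: float, noise_type: str) -> np.ndarray:
    noise = rng.normal(0.0, 1.0, size=shape)
    if noise_type == "bandlimited":
        noise = scipy.ndimage.gaussian_filter(noise, 1.0)
        noise /= noise.std()
    return sigma * noise


def degrade_map(
    sharp: DensityMap, spec: DegradeSpec
) -> tuple[DensityMap, DensityMap, DensityMap]:
    """Degrade a sharp map into (full, half1, half2) experimental-like maps.

    Signal amplitudes are attenuated by exp(-B s^2 / 4).  When
    ``local_b_amplitude`` > 0, a smooth weight field w blends the
    attenuations at B = global_b and B = global_b + local_b_amplitude
    position-wise, giving spatially varying contrast loss.  Each half map
    adds an independent noise draw; the full map is their mean.
    """
    signal = _attenuate(sharp.data, spec.global_b, sharp.voxel_size)
    if spec.local_b_amplitude > 0:
        high = _attenuate(
            sharp.data, spec.global_b + spec.local_b_amplitude, sharp.voxel_size
        )
        w = smooth_b_field(sharp.shape, spec.local_b_scale, spec.seed + 1)
        signal = (1.0 - w) * signal + w * high
    rng = np.random.default_rng(spec.seed)
    n1 = _draw_noise(rng, sharp.shape, spec.noise_sigma, spec.noise_type)
    n2 = _draw_noise(rng, sharp.shape, spec.noise_sigma, spec.noise_type)
    half1 = sharp.with_data(signal + n1)
    half2 = sharp.with_data(signal + n2)
    full = sharp.with_data(0.5 * (half1.data + half2.data))
    return full, half1, half2


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    zz, yy, xx = np.ogrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return zz**2 + yy**2 + xx**2 <= r**2


def make_mask(
    sharp: DensityMap, threshold_fraction: float = 0.05, dilation_radius: int = 2
) -> MaskVolume:
    """Tight binary mask: threshold at a fraction of the map maximum, then
    dilate by a ball of ``dilation_radius`` voxels."""
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    peak = float(sharp.data.max())
    if peak <= 0:
        raise ValueError("mask has empty support (map has no positive density)")
    mask = sharp.data >= threshold_fraction * peak
    if not mask.any():
        raise ValueError("mask has empty support")
    if dilation_radius > 0:
        mask = scipy.ndimage.binary_dilation(mask, structure=_ball(dilation_radius))
    return MaskVolume(mask.astype(np.float32), sharp.voxel_size, binary=True)


def make_target(sharp: DensityMap, mask: MaskVolume) -> DensityMap:
    """Tightly masked sharp map: voxel-wise product; zero outside the mask."""
    if mask.data.shape != sharp.shape:
        raise ValueError(f"mask shape {mask.data.shape} != map shape {sharp.shape}")
    return sharp.with_data(sharp.data * mask.data)


def generate_dataset(
    n_maps: int,
    seed: int,
    *,
    grid_shape: tuple[int, int, int] = (96, 96, 96),
    voxel_size: float = 1.0,
    n_atoms_range: tuple[int, int] = (60, 200),
    global_b_range: tuple[float, float] = (50.0, 200.0),
    peak_snr_range: tuple[float, float] = (2.0, 6.0),
    local_b_amplitude: float = 0.0,
    threshold_fraction: float = 0.05,
    dilation_radius: int = 2,
    noise_type: str = "white",
) -> list[SyntheticMapPair]:
    """Generate ``n_maps`` independent synthetic map pairs.

    Noise is parameterized by peak signal-to-noise: the noise sigma of each
    half map is the degraded-signal peak divided by a per-map peak-SNR drawn
    from ``peak_snr_range``.
    """
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    master = np.random.default_rng(seed)
    pairs: list[SyntheticMapPair] = []
    for _ in range(n_maps):
        map_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(map_seed)
        n_atoms = int(rng.integers(n_atoms_range[0], n_atoms_range[1] + 1))
        global_b = float(rng.uniform(*global_b_range))
        peak_snr = float(rng.uniform(*peak_snr_range))
        box = tuple(s * voxel_size for s in grid_shape)
        model = random_pseudo_model(n_atoms, box, map_seed + 1)
        sharp = simulate_sharp_map(model, voxel_size, grid_shape)
        attenuated = _attenuate(sharp.data, global_b, voxel_size)
        noise_sigma = float(attenuated.max()) / peak_snr
        dspec = DegradeSpec(
            global_b=global_b,
            noise_sigma=noise_sigma,
            noise_type=noise_type,
            local_b_amplitude=local_b_amplitude,
            seed=map_seed + 2,
        )
        full, half1, half2 = degrade_map(sharp, dspec)
        mask = make_mask(sharp, threshold_fraction, dilation_radius)
        target = make_target(sharp, mask)
        spec = SyntheticSpec(
            n_atoms=n_atoms,
            grid_shape=tuple(grid_shape),
            voxel_size=voxel_size,
            global_b=global_b,
            noise_sigma=noise_sigma,
            peak_snr=peak_snr,
            local_b_amplitude=local_b_amplitude,
            threshold_fraction=threshold_fraction,
            dilation_radius=dilation_radius,
            seed=map_seed,
        )
        pairs.append(SyntheticMapPair(spec, sharp, full, half1, half2, mask, target))
    return pairs


def dataset_manifest(pairs: list[SyntheticMapPair]):
    """Tabular summary (one row per map) of a generated dataset."""
    import pandas as pd

    rows = [dataclasses.asdict(p.spec) for p in pairs]
    df = pd.DataFrame(rows)
    df.insert(0, "map_id", [f"synth_{i:03d}" for i in range(len(pairs))])
    return df
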