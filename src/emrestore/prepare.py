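"""Turn map/target pairs into normalized, chunked training cubes.

For each map pair: the experimental-like input is resampled to the working
grid (if needed) and noise-normalized to (0, 0.1); the masked target is
scaled so its in-mask 95th percentile is 1; both are chunked with the same
cube grid (training stride 32, i.e. 50% overlap, by default).  Cubes are
classified *signal* if at least 1% of their voxels fall inside the tight
mask, otherwise *noise-only*; noise-only cubes are kept but subsampled so
they make up at most a configurable fraction of the set (20% by default) —
the network must see solvent-only regions to learn to suppress them, but
they must not dominate the loss.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import chunking, normalization, volume_io
from .synthetic_data import SyntheticMapPair

__all__ = ["CubeSet", "make_training_pairs"]

SIGNAL_MASK_FRACTION = 0.01


@dataclasses.dataclass
class CubeSet:
    """Paired training cubes with per-cube provenance."""

    inputs: np.ndarray  # (n, c, c, c)
    targets: np.ndarray
    map_index: np.ndarray  # (n,) which source map each cube came from
    is_signal: np.ndarray  # (n,) bool

    def __len__(self) -> int:
        return len(self.inputs)


def make_training_pairs(
    pairs: list[SyntheticMapPair],
    *,
    cube_size: int = 64,
    stride: int = 32,
    noise_cube_fraction: float = 0.2,
    max_signal_cubes_per_map: int | None = None,
    random_signal_cubes_per_map: int = 0,
    seed: int = 0,
) -> CubeSet:
    """Normalize, chunk and subsample a list of map pairs into cubes.

    When ``max_signal_cubes_per_map`` is set, the densest signal cubes are
    kept; ``random_signal_cubes_per_map`` additionally draws that many
    uniformly from the remaining signal cubes, so sparse molecule contexts
    stay represented alongside the dense anchors.
    """
    rng = np.random.default_rng(seed)
    all_in, all_tg, all_map, all_sig = [], [], [], []
    for mi, pair in enumerate(pairs):
        inp = pair.full
        if abs(inp.voxel_size - volume_io.WORKING_VOXEL_SIZE) > 1e-9:
            inp, _ = volume_io.resample_to_working_grid(inp)
        stats = normalization.estimate_noise_stats(inp)
        inp = normalization.normalize(inp, stats)
        tgt = normalization.normalize_target(pair.target, pair.mask.bool_data)
        grid = chunking.plan_chunks(inp.shape, cube_size, stride, pad_value=stats.target_mean)
        in_cubes = chunking.extract_chunks(inp.data, grid)
        tg_cubes = chunking.extract_chunks(tgt.data, grid)
        mask_cubes = chunking.extract_chunks(pair.mask.data.astype(np.float32), grid)
        frac = mask_cubes.reshape(len(grid), -1).mean(axis=1)
        signal = frac >= SIGNAL_MASK_FRACTION
        sig_idx = np.flatnonzero(signal)
        if max_signal_cubes_per_map is not None and len(sig_idx) > max_signal_cubes_per_map:
            # keep the cubes with the most in-mask content (deterministic)
            order = np.argsort(frac[sig_idx])[::-1]
            dense = sig_idx[order[:max_signal_cubes_per_map]]
            rest = sig_idx[order[max_signal_cubes_per_map:]]
            n_extra = min(random_signal_cubes_per_map, len(rest))
            extra = rng.choice(rest, size=n_extra, replace=False) if n_extra else []
            sig_idx = np.sort(np.concatenate([dense, extra]).astype(int))
        noise_idx = np.flatnonzero(~signal)
        max_noise = int(np.floor(noise_cube_fraction * len(sig_idx) / max(1e-9, 1 - noise_cube_fraction)))
        if len(noise_idx) > max_noise:
            noise_idx = np.sort(rng.choice(noise_idx, size=max_noise, replace=False))
        keep = np.concatenate([sig_idx, noise_idx]).astype(int)
        keep.sort()
        all_in.append(in_cubes[keep])
        all_tg.append(tg_cubes[keep])
        all_map.append(np.full(len(keep), mi))
        all_sig.append(signal[keep])
    return CubeSet(
        inputs=np.concatenate(all_in).astype(np.float32),
        targets=np.concatenate(all_tg).astype(np.float32),
        map_index=np.concatenate(all_map),
        is_signal=np.concatenate(all_sig),
    )
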