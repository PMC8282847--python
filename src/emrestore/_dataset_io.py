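"""Load a simulated dataset directory (maps + manifest) back into memory."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from . import volume_io
from .synthetic_data import MaskVolume, SyntheticMapPair, SyntheticSpec

__all__ = ["load_dataset_dir"]


def load_dataset_dir(path: str) -> list[SyntheticMapPair]:
    manifest = pd.read_csv(os.path.join(path, "manifest.csv"))
    pairs = []
    for _, row in manifest.iterrows():
        stem = os.path.join(path, str(row["map_id"]))
        full = volume_io.read_map(stem + "_full.mrc")
        half1 = volume_io.read_map(stem + "_half1.mrc")
        half2 = volume_io.read_map(stem + "_half2.mrc")
        target = volume_io.read_map(stem + "_target.mrc")
        mask_map = volume_io.read_map(stem + "_mask.mrc")
        mask = MaskVolume((mask_map.data > 0.5).astype(np.float32), mask_map.voxel_size)
        spec = SyntheticSpec(
            n_atoms=int(row["n_atoms"]),
            grid_shape=tuple(full.shape),
            voxel_size=float(row["voxel_size"]),
            global_b=float(row["global_b"]),
            noise_sigma=float(row["noise_sigma"]),
            peak_snr=float(row["peak_snr"]),
            local_b_amplitude=float(row["local_b_amplitude"]),
            threshold_fraction=float(row["threshold_fraction"]),
            dilation_radius=int(row["dilation_radius"]),
            seed=int(row["seed"]),
        )
        # the sharp (unmasked) reference is not persisted; the masked target
        # stands in for it wherever a reference map is needed
        pairs.append(SyntheticMapPair(spec, target, full, half1, half2, mask, target))
    return pairs
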