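"""End-to-end map post-processing: prepare -> chunk -> predict -> assemble.

Given a raw map (or a pair of half maps) and a trained model, the pipeline
(1) averages half maps if two are given, (2) resamples to the 1 A/voxel
working grid, (3) normalizes noise statistics to (0, 0.1), (4) covers the
volume with overlapping 64-voxel cubes at stride 16, (5) runs each cube
through the network, (6) reassembles by averaging overlaps, and (7) resizes
back to the original grid.  The whole chain is deterministic.

By default the output stays on the network's target scale (masked,
sharpened convention); ``denormalize=True`` maps intensities back through
the recorded normalization instead.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from . import chunking, normalization, volume_io
from .unet3d import UNetModel
from .volume_io import DensityMap

__all__ = ["InferenceConfig", "postprocess_map", "postprocess_batch"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class InferenceConfig:
    cube_size: int = 64
    stride: int = 16
    batch_size: int = 4
    denormalize: bool = False
    working_voxel_size: float = volume_io.WORKING_VOXEL_SIZE

    def __post_init__(self) -> None:
        if not 1 <= self.stride <= self.cube_size:
            raise ValueError("stride must be in [1, cube_size]")


def postprocess_map(
    input_map: DensityMap | tuple[DensityMap, DensityMap],
    model: UNetModel,
    config: InferenceConfig = InferenceConfig(),
) -> tuple[DensityMap, dict]:
    """Post-process one map (or two half maps); returns (map, metadata)."""
    if isinstance(input_map, (tuple, list)):
        half1, half2 = input_map
        raw = volume_io.average_half_maps(half1, half2)
    else:
        raw = input_map
    if hasattr(model, "validate_weights"):
        model.validate_weights()
    if config.cube_size % model.config.divisor != 0:
        raise ValueError(
            f"cube size {config.cube_size} incompatible with model divisor "
            f"{model.config.divisor}"
        )
    working, record = volume_io.resample_to_working_grid(raw, config.working_voxel_size)
    stats = normalization.estimate_noise_stats(working)
    normed = normalization.normalize(working, stats)
    grid = chunking.plan_chunks(
        normed.shape, config.cube_size, config.stride, pad_value=stats.target_mean
    )
    cubes = chunking.extract_chunks(normed.data, grid)
    out_cubes = np.empty_like(cubes)
    for i in range(0, len(cubes), config.batch_size):
        out_cubes[i : i + config.batch_size] = model.forward(cubes[i : i + config.batch_size])
    assembled = chunking.assemble_chunks(out_cubes, grid, normed.shape)
    result_working = DensityMap(assembled, normed.voxel_size, normed.origin)
    if config.denormalize:
        result_working = normalization.denormalize(result_working, stats)
    result = volume_io.resize_to_original(result_working, record)
    meta = {
        "normalization": stats.to_dict(),
        "n_chunks": len(grid),
        "working_shape": list(normed.shape),
        "original_shape": list(record.original_shape),
        "cube_size": config.cube_size,
        "stride": config.stride,
        "denormalized": config.denormalize,
    }
    return result, meta


def postprocess_batch(
    paths: list,
    model: UNetModel,
    config: InferenceConfig,
    output_dir,
    *,
    checkpoint_id: str = "",
) -> tuple[list, "object"]:
    """Post-process many maps, isolating per-map failures.

    Returns (list of output paths or None per input, manifest DataFrame).
    Raises RuntimeError only if every map failed.
    """
    import os

    import pandas as pd

    os.makedirs(output_dir, exist_ok=True)
    out_paths: list = []
    rows = []
    for path in paths:
        row: dict = {"input": str(path), "checkpoint": checkpoint_id}
        try:
            dmap = volume_io.read_map(path)
            result, meta = postprocess_map(dmap, model, config)
            base = os.path.splitext(os.path.basename(str(path)))[0]
            out_path = os.path.join(str(output_dir), f"{base}_restored.mrc")
            volume_io.write_map(result, out_path)
            row.update(
                status="ok",
                output=out_path,
                noise_mean=meta["normalization"]["noise_mean"],
                noise_std=meta["normalization"]["noise_std"],
                n_chunks=meta["n_chunks"],
            )
            out_paths.append(out_path)
        except Exception as exc:  # continue-on-error per map
            logger.error("failed to process %s: %s", path, exc)
            row.update(status="failed", output=None, error=str(exc))
            out_paths.append(None)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if all(p is None for p in out_paths):
        raise RuntimeError("all maps failed to process")
    return out_paths, manifest
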