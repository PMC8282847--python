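"""3D U-net regression model for cube-wise map restoration.

The network maps a normalized 64x64x64 input cube to a post-processed cube
of the same size.  Architecture: an encoder of three levels, each a block
of three convolutions (kernel 3, same padding) with group normalization and
PReLU, with stride-2 strided convolutions between levels; a mirrored
decoder using kernel-2 stride-2 transposed convolutions and concatenation
skip connections; and a final linear 1x1x1 convolution to one channel.
Default channel widths are 32/64/128 per level.

Because group normalization never mixes samples, the forward pass is
deterministic and independent of batch composition; there is no separate
train/eval behaviour.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .layers import Conv3d, ConvTranspose3d, GroupNorm, PReLU, Layer

__all__ = ["UNetConfig", "UNetModel", "build_model", "count_parameters", "save_model", "load_model"]


@dataclasses.dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters of the volumetric U-net."""

    n_levels: int = 3
    convs_per_block: int = 3
    base_filters: tuple[int, ...] = (32, 64, 128)
    kernel_size: int = 3
    norm_groups: int = 8
    prelu_init_slope: float = 0.25
    in_channels: int = 1
    out_channels: int = 1
    #: down-scaling of the final projection's He init.  Group normalization
    #: pins internal activations at O(1) while the masked targets are much
    #: smaller, so a small final layer starts training near the zero map
    #: (the better constant predictor) without cutting off backpropagation.
    final_init_scale: float = 0.1

    def __post_init__(self) -> None:
        if len(self.base_filters) != self.n_levels:
            raise ValueError(
                f"base_filters {self.base_filters} must have n_levels={self.n_levels} entries"
            )
        for f in self.base_filters:
            if f % self.norm_groups != 0:
                raise ValueError(
                    f"channel count {f} not divisible by norm_groups={self.norm_groups}"
                )

    @property
    def divisor(self) -> int:
        """Spatial dimensions must be divisible by this (2^(n_levels-1))."""
        return 2 ** (self.n_levels - 1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "UNetConfig":
        d = dict(d)
        d["base_filters"] = tuple(d["base_filters"])
        return cls(**d)


def _conv_block(c_in, c_out, cfg: UNetConfig, rng, dtype) -> list[Layer]:
    layers: list[Layer] = []
    c = c_in
    for _ in range(cfg.convs_per_block):
        layers.append(Conv3d(c, c_out, cfg.kernel_size, 1, rng=rng, dtype=dtype))
        layers.append(GroupNorm(c_out, cfg.norm_groups, dtype=dtype))
        layers.append(PReLU(c_out, cfg.prelu_init_slope, dtype=dtype))
        c = c_out
    return layers


class UNetModel:
    """Realized trainable U-net; see module docstring for the topology."""

    def __init__(self, config: UNetConfig, seed: int, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        f = config.base_filters
        n = config.n_levels
        self.enc_blocks = []
        for i in range(n):
            c_in = config.in_channels if i == 0 else f[i]
            self.enc_blocks.append(_conv_block(c_in, f[i], config, rng, dtype))
        self.downs = [
            Conv3d(f[i], f[i + 1], config.kernel_size, 2, rng=rng, dtype=dtype)
            for i in range(n - 1)
        ]
        self.ups = [
            ConvTranspose3d(f[i + 1], f[i], rng=rng, dtype=dtype) for i in range(n - 1)
        ]
        self.dec_blocks = [
            _conv_block(2 * f[i], f[i], config, rng, dtype) for i in range(n - 1)
        ]
        self.final = Conv3d(f[0], config.out_channels, 1, 1, rng=rng, dtype=dtype)
        self.final.params["W"] *= config.final_init_scale

    # -- plumbing ---------------------------------------------------------

    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for block in self.enc_blocks:
            out.extend(block)
        out.extend(self.downs)
        out.extend(self.ups)
        for block in self.dec_blocks:
            out.extend(block)
        out.append(self.final)
        return out

    def named_params(self) -> dict[str, np.ndarray]:
        names: dict[str, np.ndarray] = {}

        def add(prefix, block):
            for j, layer in enumerate(block):
                for k, v in layer.params.items():
                    names[f"{prefix}.{j}.{k}"] = v

        for i, b in enumerate(self.enc_blocks):
            add(f"enc{i}", b)
        add("down", self.downs)
        add("up", self.ups)
        for i, b in enumerate(self.dec_blocks):
            add(f"dec{i}", b)
        add("final", [self.final])
        return names

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_params().items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        params = self.named_params()
        if set(params) != set(weights):
            raise ValueError("weight dictionary does not match model parameters")
        for k, v in params.items():
            if weights[k].shape != v.shape:
                raise ValueError(f"shape mismatch for {k}")
            v[...] = weights[k]

    # -- computation ------------------------------------------------------

    def _check_spatial(self, shape) -> None:
        d = self.config.divisor
        if any(s % d != 0 for s in shape):
            raise ValueError(f"spatial dims {tuple(shape)} must be divisible by {d}")

    def validate_weights(self) -> None:
        """Raise if any parameter is NaN/Inf (checked at pipeline entry
        points, not per forward pass)."""
        for name, w in self.named_params().items():
            if not np.all(np.isfinite(w)):
                raise FloatingPointError(f"model weights contain NaN/Inf ({name})")

    def forward(self, cubes: np.ndarray) -> np.ndarray:
        """Batch forward pass: ``(B, D, H, W)`` cubes in, same shape out."""
        x = np.asarray(cubes, dtype=self.dtype)
        squeeze = x.ndim == 4
        if squeeze:
            x = x[..., None]
        self._check_spatial(x.shape[1:4])
        n = self.config.n_levels
        skips = []
        h = x
        for i in range(n):
            for layer in self.enc_blocks[i]:
                h = layer.forward(h)
            if i < n - 1:
                skips.append(h)
                h = self.downs[i].forward(h)
        self._skip_channels = [s.shape[-1] for s in skips]
        for i in reversed(range(n - 1)):
            h = self.ups[i].forward(h)
            h = np.concatenate([skips[i], h], axis=-1)
            for layer in self.dec_blocks[i]:
                h = layer.forward(h)
        y = self.final.forward(h)
        return y[..., 0] if squeeze else y

    def backward(self, gout: np.ndarray) -> None:
        """Backpropagate loss gradient ``gout`` (same shape as forward output),
        accumulating parameter gradients in the layers."""
        g = np.asarray(gout, dtype=self.dtype)
        if g.ndim == 4:
            g = g[..., None]
        g = self.final.backward(g)
        n = self.config.n_levels
        skip_grads: dict[int, np.ndarray] = {}
        for i in range(n - 1):
            for layer in reversed(self.dec_blocks[i]):
                g = layer.backward(g)
            cs = self._skip_channels[i]
            skip_grads[i] = g[..., :cs]
            g = self.ups[i].backward(np.ascontiguousarray(g[..., cs:]))
        for i in reversed(range(n)):
            if i < n - 1:
                g = self.downs[i].backward(g)
                g = g + skip_grads[i]
            for layer in reversed(self.enc_blocks[i]):
                g = layer.backward(g)

    __call__ = forward


def build_model(config: UNetConfig, seed: int, dtype=np.float32) -> UNetModel:
    """Instantiate a U-net with He-initialized weights (deterministic per seed)."""
    return UNetModel(config, seed, dtype)


def count_parameters(model: UNetModel) -> int:
    """Exact number of trainable scalar parameters."""
    return int(sum(v.size for v in model.named_params().values()))


def save_model(model: UNetModel, path: str) -> None:
    """Serialize weights + config to an .npz with a JSON config sidecar."""
    arrays = model.get_weights()
    arrays["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)
    with open(str(path) + ".json", "w") as fh:
        json.dump(model.config.to_dict(), fh, indent=2)


def load_model(path: str) -> UNetModel:
    with np.load(path) as npz:
        cfg = UNetConfig.from_dict(json.loads(bytes(npz["__config__"]).decode()))
        weights = {k: npz[k] for k in npz.files if k != "__config__"}
    model = build_model(cfg, seed=0)
    model.set_weights(weights)
    return model
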