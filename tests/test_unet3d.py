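"""Architecture contracts, determinism and gradient correctness."""

import numpy as np
import pytest

from emrestore.layers import Conv3d, ConvTranspose3d, GroupNorm, PReLU
from emrestore.unet3d import (
    UNetConfig,
    build_model,
    count_parameters,
    load_model,
    save_model,
)

TINY = UNetConfig(base_filters=(2, 4, 8), norm_groups=2, convs_per_block=2)


class TestShapes:
    @pytest.mark.parametrize("n", [8, 12, 16])
    def test_output_shape_preserved(self, n, rng):
        model = build_model(TINY, seed=0)
        x = rng.normal(size=(1, n, n, n)).astype(np.float32)
        assert model.forward(x).shape == x.shape

    def test_indivisible_dims_rejected(self, rng):
        model = build_model(TINY, seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(rng.normal(size=(1, 10, 10, 10)))

    def test_zero_weights_zero_output(self, rng):
        model = build_model(TINY, seed=0)
        weights = {k: np.zeros_like(v) for k, v in model.get_weights().items()}
        model.set_weights(weights)
        out = model.forward(np.zeros((1, 8, 8, 8), np.float32))
        np.testing.assert_array_equal(out, 0.0)

    def test_invalid_group_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            UNetConfig(base_filters=(3, 6, 12), norm_groups=2)


class TestDeterminism:
    def test_same_seed_same_outputs(self, rng):
        x = rng.normal(size=(1, 8, 8, 8)).astype(np.float32)
        y1 = build_model(TINY, seed=7).forward(x)
        y2 = build_model(TINY, seed=7).forward(x)
        np.testing.assert_array_equal(y1, y2)
        y3 = build_model(TINY, seed=8).forward(x)
        assert not np.array_equal(y1, y3)

    def test_repeated_forward_bitwise_identical(self, rng):
        model = build_model(TINY, seed=0)
        x = rng.normal(size=(2, 8, 8, 8)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_batch_composition_invariance(self, rng):
        """Group norm statistics are per-sample: a cube's output must not
        depend on what else is in the batch."""
        model = build_model(TINY, seed=0)
        a = rng.normal(size=(8, 8, 8)).astype(np.float32)
        b = rng.normal(size=(8, 8, 8)).astype(np.float32)
        alone = model.forward(a[None])[0]
        batched = model.forward(np.stack([a, b]))[0]
        np.testing.assert_allclose(alone, batched, atol=1e-5)

    def test_batch_order_permutation(self, rng):
        model = build_model(TINY, seed=0)
        x = rng.normal(size=(3, 8, 8, 8)).astype(np.float32)
        y = model.forward(x)
        y_perm = model.forward(x[::-1].copy())
        np.testing.assert_allclose(y_perm, y[::-1], atol=1e-5)


class TestParameterCount:
    def test_toy_closed_form(self):
        """1 level, 1 conv, 2 filters, kernel 3: conv(1->2): 2*27+2 = 56,
        GN: 2+2, PReLU: 2, final 1x1x1 conv(2->1): 2+1."""
        cfg = UNetConfig(
            n_levels=1, convs_per_block=1, base_filters=(2,), norm_groups=1
        )
        model = build_model(cfg, seed=0)
        assert count_parameters(model) == (2 * 27 + 2) + 4 + 2 + (2 + 1)

    def test_halving_filters_quarters_count(self):
        big = count_parameters(build_model(UNetConfig(base_filters=(8, 16, 32), norm_groups=4), 0))
        small = count_parameters(build_model(UNetConfig(base_filters=(4, 8, 16), norm_groups=4), 0))
        assert big / 4 <= small <= big / 2

    def test_positive(self):
        assert count_parameters(build_model(TINY, 0)) > 0


class TestGradients:
    """Finite-difference checks pin every backward pass."""

    @pytest.mark.parametrize(
        "layer_fn,in_ch",
        [
            (lambda rng: Conv3d(3, 4, 3, 1, rng=rng, dtype=np.float64), 3),
            (lambda rng: Conv3d(3, 4, 3, 2, rng=rng, dtype=np.float64), 3),
            (lambda rng: Conv3d(3, 4, 1, 1, rng=rng, dtype=np.float64), 3),
            (lambda rng: ConvTranspose3d(3, 4, rng=rng, dtype=np.float64), 3),
            (lambda rng: GroupNorm(4, 2, dtype=np.float64), 4),
            (lambda rng: PReLU(4, dtype=np.float64), 4),
        ],
        ids=["conv3", "conv3s2", "conv1", "convT", "groupnorm", "prelu"],
    )
    def test_layer_gradcheck(self, layer_fn, in_ch, rng):
        layer = layer_fn(rng)
        x = rng.normal(size=(2, 6, 6, 6, in_ch))
        y = layer.forward(x)
        t = rng.normal(size=y.shape)

        def loss():
            return np.mean(np.abs(layer.forward(x) - t))

        g = np.sign(y - t) / y.size
        layer.zero_grad()
        gx = layer.backward(g)
        eps = 1e-6
        for name, p in layer.params.items():
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp = loss()
                p[idx] = orig - eps
                lm = loss()
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert layer.grads[name][idx] == pytest.approx(num, rel=1e-3, abs=1e-7), name
        for _ in range(3):
            idx = tuple(rng.integers(0, s) for s in x.shape)
            orig = x[idx]
            x[idx] = orig + eps
            lp = loss()
            x[idx] = orig - eps
            lm = loss()
            x[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert gx[idx] == pytest.approx(num, rel=1e-3, abs=1e-7)

    def test_full_model_gradcheck(self, rng):
        model = build_model(TINY, seed=0, dtype=np.float64)
        x = rng.normal(size=(1, 8, 8, 8))
        t = rng.normal(size=(1, 8, 8, 8))
        y = model.forward(x)
        for layer in model.layers():
            layer.zero_grad()
        model.backward(np.sign(y - t) / y.size)
        params = model.named_params()
        grads = {}
        for prefix, block in (
            [("enc%d" % i, b) for i, b in enumerate(model.enc_blocks)]
            + [("down", model.downs), ("up", model.ups)]
            + [("dec%d" % i, b) for i, b in enumerate(model.dec_blocks)]
            + [("final", [model.final])]
        ):
            for j, layer in enumerate(block):
                for k, g in layer.grads.items():
                    grads[f"{prefix}.{j}.{k}"] = g
        eps = 1e-6
        check = rng.choice(sorted(params), size=8, replace=False)
        for name in check:
            p = params[name]
            idx = tuple(rng.integers(0, s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp = np.mean(np.abs(model.forward(x) - t))
            p[idx] = orig - eps
            lm = np.mean(np.abs(model.forward(x) - t))
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert grads[name][idx] == pytest.approx(num, rel=1e-3, abs=1e-7), name


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = build_model(TINY, seed=3)
        x = rng.normal(size=(1, 8, 8, 8)).astype(np.float32)
        y = model.forward(x)
        path = tmp_path / "model.npz"
        save_model(model, str(path))
        loaded = load_model(str(path))
        assert loaded.config == model.config
        np.testing.assert_array_equal(loaded.forward(x), y)
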