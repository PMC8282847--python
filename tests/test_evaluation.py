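"""FSC computation, threshold resolution and real-space correlation."""

import numpy as np
import pytest

from emrestore.evaluation import (
    FSCCurve,
    fsc,
    masked_fsc,
    real_space_cc,
    resolution_at_threshold,
    soften_mask,
)
from emrestore.synthetic_data import (
    DegradeSpec,
    MaskVolume,
    degrade_map,
    make_mask,
    random_pseudo_model,
    simulate_sharp_map,
)
from emrestore.volume_io import DensityMap


def _brute_force_shells(a, b):
    """Direct-DFT FSC oracle for tiny cubic maps (no FFT library)."""
    n = a.shape[0]
    idx = np.arange(n)
    # DFT matrix
    W = np.exp(-2j * np.pi * np.outer(idx, idx) / n)
    fa = np.einsum("zi,yj,xk,ijk->zyx", W, W, W, a.astype(complex))
    fb = np.einsum("zi,yj,xk,ijk->zyx", W, W, W, b.astype(complex))
    freq = np.fft.fftfreq(n) * n
    zz, yy, xx = np.meshgrid(freq, freq, freq, indexing="ij")
    shell = np.rint(np.sqrt(zz**2 + yy**2 + xx**2)).astype(int)
    n_shells = n // 2 + 1
    out = []
    for s in range(n_shells):
        sel = shell == s
        cross = np.sum(fa[sel] * np.conj(fb[sel])).real
        out.append(cross / np.sqrt(np.sum(np.abs(fa[sel]) ** 2) * np.sum(np.abs(fb[sel]) ** 2)))
    return np.array(out)


class TestFSC:
    def test_self_correlation_is_one(self, noise_map):
        curve = fsc(noise_map, noise_map)
        np.testing.assert_allclose(curve.fsc, 1.0, atol=1e-9)

    def test_sign_flip_is_minus_one(self, noise_map):
        neg = noise_map.with_data(-noise_map.data)
        curve = fsc(noise_map, neg)
        np.testing.assert_allclose(curve.fsc, -1.0, atol=1e-9)

    def test_symmetry_and_scale_invariance(self, rng):
        a = DensityMap(rng.normal(size=(16, 16, 16)), 1.0)
        b = DensityMap(rng.normal(size=(16, 16, 16)), 1.0)
        c1, c2 = fsc(a, b), fsc(b, a)
        np.testing.assert_array_equal(c1.fsc, c2.fsc)
        scaled = fsc(a.with_data(7.5 * a.data), b)
        np.testing.assert_allclose(scaled.fsc, c1.fsc, atol=1e-7)

    def test_matches_brute_force_dft(self, rng):
        a = rng.normal(size=(8, 8, 8))
        b = a + 0.5 * rng.normal(size=(8, 8, 8))
        expected = _brute_force_shells(a, b)
        curve = fsc(DensityMap(a, 1.0), DensityMap(b, 1.0))
        np.testing.assert_allclose(curve.fsc, expected, rtol=1e-6, atol=1e-9)

    def test_independent_noise_near_zero(self, rng):
        a = DensityMap(rng.normal(size=(64, 64, 64)), 1.0)
        b = DensityMap(rng.normal(size=(64, 64, 64)), 1.0)
        curve = fsc(a, b)
        bound = 3.0 / np.sqrt(curve.n_voxels[1:])
        frac_ok = np.mean(np.abs(curve.fsc[1:]) <= bound)
        assert frac_ok >= 0.95

    def test_all_zero_rejected(self):
        z = DensityMap(np.zeros((8, 8, 8)), 1.0)
        with pytest.raises(ValueError, match="all-zero"):
            fsc(z, z)


class TestResolutionAtThreshold:
    def test_worked_interpolation_example(self):
        curve = FSCCurve(
            shell_freq=np.array([0.0, 0.1, 0.2, 0.3]),
            fsc=np.array([1.0, 0.9, 0.6, 0.2]),
            n_voxels=np.array([1, 10, 20, 30]),
            voxel_size=1.0,
        )
        res = resolution_at_threshold(curve, 0.5)
        assert res == pytest.approx(1.0 / 0.225, abs=1e-3)
        assert res == pytest.approx(4.444, abs=1e-3)

    def test_never_crossing_returns_nyquist(self, noise_map):
        res = resolution_at_threshold(fsc(noise_map, noise_map), 0.5)
        assert res == pytest.approx(2.0 * noise_map.voxel_size)
        assert res.reached_nyquist

    def test_below_from_start_is_inf(self, rng):
        a = DensityMap(rng.normal(size=(32, 32, 32)), 1.0)
        b = DensityMap(rng.normal(size=(32, 32, 32)), 1.0)
        res = resolution_at_threshold(fsc(a, b), 0.5)
        assert np.isinf(res)
        assert res.below_from_start

    def test_monotone_in_noise(self, rng):
        model = random_pseudo_model(40, 48.0, seed=5)
        sharp = simulate_sharp_map(model, 1.0, (48, 48, 48))
        results = []
        for sigma in (0.02, 0.1, 0.4):
            spec = DegradeSpec(global_b=80.0, noise_sigma=sigma, seed=9)
            _, h1, h2 = degrade_map(sharp, spec)
            res = resolution_at_threshold(fsc(h1, h2), 0.143)
            results.append(float(res))
        assert results[0] < results[1] < results[2]


class TestMaskedFSC:
    def test_all_ones_mask_is_noop(self, rng):
        a = DensityMap(rng.normal(size=(16, 16, 16)), 1.0)
        b = DensityMap(rng.normal(size=(16, 16, 16)), 1.0)
        mask = MaskVolume(np.ones((16, 16, 16), np.float32), 1.0)
        np.testing.assert_allclose(
            masked_fsc(a, b, mask, 3.0).fsc, fsc(a, b).fsc, atol=1e-9
        )

    def test_self_masked_is_one(self, rng):
        a = DensityMap(rng.normal(size=(16, 16, 16)) + 1.0, 1.0)
        m = np.zeros((16, 16, 16), np.float32)
        m[4:12, 4:12, 4:12] = 1.0
        curve = masked_fsc(a, a, MaskVolume(m, 1.0), soften_width=2.0)
        np.testing.assert_allclose(curve.fsc, 1.0, atol=1e-9)

    def test_masking_out_noise_raises_fsc(self, rng):
        model = random_pseudo_model(40, 48.0, seed=3)
        sharp = simulate_sharp_map(model, 1.0, (48, 48, 48))
        mask = make_mask(sharp, 0.05, 2)
        # noise confined outside the mask
        noise = rng.normal(0, 0.3, size=(48, 48, 48)) * (1 - mask.data)
        a = sharp.with_data(sharp.data + noise)
        b = sharp
        plain = fsc(a, b)
        masked = masked_fsc(a, b, mask, 2.0)
        mid = slice(3, len(plain.fsc) // 2)
        assert masked.fsc[mid].mean() > plain.fsc[mid].mean()

    def test_soften_mask_profile(self):
        m = np.zeros((16, 16, 16), np.float32)
        m[8, 8, 8] = 1.0
        soft = soften_mask(MaskVolume(m, 1.0), width=2.0)
        assert soft[8, 8, 8] == 1.0
        assert soft[8, 8, 9] == pytest.approx(0.5)  # cos(pi/2) edge midpoint
        assert soft[8, 8, 12] == 0.0


class TestRealSpaceCC:
    def test_self_and_affine(self, noise_map):
        assert real_space_cc(noise_map, noise_map) == pytest.approx(1.0)
        aff = noise_map.with_data(3.0 * noise_map.data + 2.0)
        assert real_space_cc(noise_map, aff) == pytest.approx(1.0)
        neg = noise_map.with_data(-2.0 * noise_map.data)
        assert real_space_cc(noise_map, neg) == pytest.approx(-1.0)

    def test_decreases_with_noise(self, rng):
        sig = rng.normal(size=(32, 32, 32))
        base = DensityMap(sig, 1.0)
        ccs = [
            real_space_cc(base, DensityMap(sig + s * rng.normal(size=sig.shape), 1.0))
            for s in (0.1, 0.5, 1.0, 2.0)
        ]
        assert all(a > b for a, b in zip(ccs, ccs[1:]))

    def test_zero_variance_rejected(self, noise_map):
        flat = noise_map.with_data(np.zeros(noise_map.shape))
        with pytest.raises(ValueError, match="zero variance"):
            real_space_cc(noise_map, flat)
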