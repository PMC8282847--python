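"""Map I/O, half-map averaging and working-grid resampling."""

import numpy as np
import pytest

from emrestore.volume_io import (
    DensityMap,
    ResampleRecord,
    average_half_maps,
    fourier_resize,
    read_map,
    resample_to_working_grid,
    resize_to_original,
    write_map,
)


def _write_raw_mrc(path, data_zyx, voxel, axis_order=(1, 2, 3)):
    """Independent minimal MRC2014 writer (test oracle, no gemmi).

    ``axis_order`` is (MAPC, MAPR, MAPS): which crystal axis (1=X,2=Y,3=Z)
    varies fastest/medium/slowest in the file.
    """
    nz, ny, nx = data_zyx.shape
    # file stores axes (fastest, medium, slow) = axis_order; build that array
    perm = [3 - axis_order[2 - i] for i in range(3)]  # file slow->fast as zyx indices
    stored = np.transpose(data_zyx, perm).astype("<f4")
    n_file = stored.shape  # (slow, mid, fast)
    header = np.zeros(256, dtype="<i4")
    header[0:3] = n_file[::-1]  # NC, NR, NS (fast, mid, slow)
    header[3] = 2  # mode float32
    dims_xyz = np.array([nx, ny, nz])
    header[7:10] = dims_xyz  # MX, MY, MZ
    header[10:13] = np.array([nx, ny, nz], dtype="<i4") * 0  # placeholder
    fheader = header.view("<f4")
    fheader[10:13] = dims_xyz * voxel  # cell lengths
    fheader[13:16] = 90.0
    header[16:19] = axis_order
    fheader[19] = stored.min()
    fheader[20] = stored.max()
    fheader[21] = stored.mean()
    header[22] = 1  # ISPG
    header[52] = int.from_bytes(b"MAP ", "little")
    header[53] = 16708  # little-endian machine stamp
    with open(path, "wb") as fh:
        fh.write(header.tobytes())
        fh.write(stored.tobytes())


class TestReadWrite:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        data = rng.normal(size=(16, 12, 10)).astype(np.float32)
        dmap = DensityMap(data, 1.5, origin=(10.0, 20.0, 30.0))
        p = tmp_path / "m.mrc"
        write_map(dmap, p)
        back = read_map(p)
        np.testing.assert_array_equal(back.data, data)
        assert back.voxel_size == pytest.approx(1.5)
        assert back.origin == pytest.approx((10.0, 20.0, 30.0))

    def test_reads_independent_writer(self, tmp_path, rng):
        data = rng.normal(size=(8, 8, 8)).astype(np.float32)
        p = tmp_path / "raw.mrc"
        _write_raw_mrc(p, data, voxel=2.0)
        back = read_map(p)
        np.testing.assert_allclose(back.data, data, rtol=1e-6)
        assert back.voxel_size == pytest.approx(2.0)

    def test_permuted_axis_order_canonicalized(self, tmp_path, rng):
        data = rng.normal(size=(6, 8, 10)).astype(np.float32)
        p1 = tmp_path / "xyz.mrc"
        p2 = tmp_path / "zyx.mrc"
        _write_raw_mrc(p1, data, voxel=1.0, axis_order=(1, 2, 3))
        _write_raw_mrc(p2, data, voxel=1.0, axis_order=(3, 2, 1))
        m1, m2 = read_map(p1), read_map(p2)
        np.testing.assert_allclose(m1.data, m2.data, rtol=1e-6)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_map(tmp_path / "nope.mrc")

    def test_anisotropic_rejected(self, tmp_path, rng):
        import gemmi

        data = rng.normal(size=(8, 8, 8)).astype(np.float32)
        grid = gemmi.FloatGrid(8, 8, 8)
        np.asarray(grid)[...] = data.T
        grid.unit_cell = gemmi.UnitCell(8.0, 8.0, 16.0, 90, 90, 90)
        grid.spacegroup = gemmi.SpaceGroup("P1")
        ccp4 = gemmi.Ccp4Map()
        ccp4.grid = grid
        ccp4.update_ccp4_header()
        p = tmp_path / "aniso.mrc"
        ccp4.write_ccp4_map(str(p))
        with pytest.raises(ValueError, match="anisotropic"):
            read_map(p)
        m = read_map(p, allow_anisotropic=True)
        assert m.voxel_size == pytest.approx((1.0 + 1.0 + 2.0) / 3)

    def test_nan_rejected(self):
        data = np.zeros((4, 4, 4))
        data[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            DensityMap(data, 1.0)


class TestAverageHalfMaps:
    def test_identity_and_symmetry(self, noise_map):
        v = noise_map
        same = average_half_maps(v, v)
        np.testing.assert_allclose(same.data, v.data, rtol=1e-6)
        plus = v.with_data(v.data + 1.0)
        minus = v.with_data(v.data - 1.0)
        np.testing.assert_allclose(average_half_maps(plus, minus).data, v.data, rtol=1e-5, atol=1e-6)

    def test_noise_variance_halved(self, rng):
        signal = np.zeros((64, 64, 64))
        sigma = 2.0
        h1 = DensityMap(signal + rng.normal(0, sigma, signal.shape), 1.0)
        h2 = DensityMap(signal + rng.normal(0, sigma, signal.shape), 1.0)
        full = average_half_maps(h1, h2)
        assert full.data.var() == pytest.approx(sigma**2 / 2, rel=0.05)

    def test_shape_mismatch(self, noise_map):
        other = DensityMap(np.zeros((8, 8, 8)), 1.0)
        with pytest.raises(ValueError):
            average_half_maps(noise_map, other)


class TestResample:
    def test_factor_two_shape(self, gaussian_blob_map):
        out, record = resample_to_working_grid(gaussian_blob_map, 1.0)
        assert out.shape == (64, 64, 64)
        assert out.voxel_size == 1.0
        assert record.original_shape == (32, 32, 32)

    def test_noop_at_target_voxel(self, noise_map):
        out, _ = resample_to_working_grid(noise_map, 1.0)
        np.testing.assert_allclose(out.data, noise_map.data, rtol=1e-6)

    def test_band_limited_round_trip(self, gaussian_blob_map):
        up, record = resample_to_working_grid(gaussian_blob_map, 1.0)
        back = resize_to_original(up, record)
        assert back.shape == gaussian_blob_map.shape
        assert back.voxel_size == gaussian_blob_map.voxel_size
        cc = np.corrcoef(back.data.ravel(), gaussian_blob_map.data.ravel())[0, 1]
        assert cc > 0.999

    def test_linearity(self, rng):
        a = rng.normal(size=(16, 16, 16))
        b = rng.normal(size=(16, 16, 16))
        lhs = fourier_resize(2.0 * a + 3.0 * b, (24, 24, 24))
        rhs = 2.0 * fourier_resize(a, (24, 24, 24)) + 3.0 * fourier_resize(b, (24, 24, 24))
        np.testing.assert_allclose(lhs, rhs, rtol=1e-4, atol=1e-5)

    def test_degenerate_output_shape(self):
        tiny = DensityMap(np.ones((4, 4, 4)), 0.5)
        with pytest.raises(ValueError, match="degenerate"):
            resample_to_working_grid(tiny, 1.0)

    def test_degenerate_record(self):
        with pytest.raises(ValueError):
            ResampleRecord((0, 0, 0), 1.0, (0, 0, 0))

    def test_spline_method_available(self, gaussian_blob_map):
        out, record = resample_to_working_grid(gaussian_blob_map, 1.0, method="spline")
        assert out.shape == (64, 64, 64)
        back = resize_to_original(out, record, method="spline")
        cc = np.corrcoef(back.data.ravel(), gaussian_blob_map.data.ravel())[0, 1]
        assert cc > 0.99
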