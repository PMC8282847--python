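"""Independent numerical oracles shared across test modules."""

import numpy as np
import scipy.fft


def guinier_slope(sharp, degraded, voxel_size, s2_max=0.02):
    """Slope of log radial power ratio vs s^2 (Guinier-style fit).

    For amplitude attenuation exp(-B s^2/4), power attenuates as
    exp(-B s^2/2), so the fitted slope equals -B/2.
    """
    f1 = np.abs(scipy.fft.fftn(sharp.astype(np.float64))) ** 2
    f2 = np.abs(scipy.fft.fftn(degraded.astype(np.float64))) ** 2
    n = sharp.shape[0]
    freq = scipy.fft.fftfreq(n, d=voxel_size)
    zz, yy, xx = np.meshgrid(freq, freq, freq, indexing="ij", sparse=True)
    s2 = zz**2 + yy**2 + xx**2
    shell = np.rint(np.sqrt(s2) * n * voxel_size).astype(int)
    n_shells = n // 2
    p1 = np.bincount(shell.ravel(), f1.ravel(), minlength=n_shells)[:n_shells]
    p2 = np.bincount(shell.ravel(), f2.ravel(), minlength=n_shells)[:n_shells]
    s2_shell = np.bincount(shell.ravel(), s2.ravel(), minlength=n_shells)[:n_shells]
    cnt = np.bincount(shell.ravel(), minlength=n_shells)[:n_shells]
    s2_shell = s2_shell / cnt
    sel = (s2_shell > 1e-5) & (s2_shell < s2_max) & (p1 > 0)
    return np.polyfit(s2_shell[sel], np.log(p2[sel] / p1[sel]), 1)[0]
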