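"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately avoid the implementation's code paths: quadrature instead
of closed forms, exhaustive search instead of morphology/distance transforms.
"""

import numpy as np
from scipy.signal import fftconvolve
from scipy.spatial.distance import cdist


def brute_force_convolution(ktrans, ve, vp, aif, frame_times, dt=0.01):
    """Trapezoidal convolution of the AIF with the exchange kernel on a fine
    grid — the independent quadrature oracle for the closed-form tissue curve.

    The AIF jumps at bolus arrival, so the integrand is only piecewise
    smooth: the plain trapezoid rule books a spurious half-interval
    dt/2 * Cp(onset) * kernel(t - onset) for the grid cell just before the
    jump. Subtracting that term restores second-order accuracy everywhere,
    including at the onset frame itself.
    """
    t_end = float(frame_times[-1])
    n = int(round(t_end / dt)) + 1
    tt = np.arange(n) * dt
    cp = aif.plasma_concentration(tt)
    onset_idx = int(round(aif.onset_time / dt))
    kep_s = (ktrans / ve) / 60.0
    kernel = np.exp(-kep_s * tt)
    conv = fftconvolve(cp, kernel)[:n] * dt
    conv -= 0.5 * dt * cp * kernel[0]  # trapezoid end correction (cp[0] = 0)
    if 0 <= onset_idx < n:
        jump = cp[onset_idx]
        corr = np.zeros(n)
        corr[onset_idx:] = 0.5 * dt * jump * kernel[: n - onset_idx]
        conv -= corr
    ct = vp * aif.plasma_concentration(tt) + (ktrans / 60.0) * conv
    idx = np.round(np.asarray(frame_times) / dt).astype(int)
    return ct[idx]


def brute_force_shell_index(mask: np.ndarray) -> np.ndarray:
    """Shell index = city-block distance to the nearest outside voxel
    (array border counts as outside), by exhaustive nearest-outside search."""
    padded = np.pad(mask, 1, constant_values=False)
    inside = np.argwhere(padded)
    outside = np.argwhere(~padded)
    d = cdist(inside, outside, metric="cityblock").min(axis=1)
    out = np.zeros(padded.shape, dtype=int)
    out[tuple(inside.T)] = d.astype(int)
    return out[1:-1, 1:-1, 1:-1]
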