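"""Small numerical helpers shared across modules."""

from __future__ import annotations

import numpy as np

#: speed of light in cm/ps; converts wavenumber (cm^-1) to frequency (1/ps)
C_CM_PER_PS = 2.99792458e-2

#: nm <-> cm^-1 conversion constant: wavenumber = NM_CM / wavelength_nm
NM_TO_WAVENUMBER = 1.0e7


def wavenumber_from_nm(wavelength_nm):
    """Vacuum wavenumber in cm^-1 from wavelength in nm."""
    return NM_TO_WAVENUMBER / np.asarray(wavelength_nm, dtype=float)


def parabolic_peak(x: np.ndarray, y: np.ndarray) -> float:
    """Sub-sample peak position by a parabola through the maximum and its
    neighbours.

    Ties between equal maxima are broken toward larger ``x`` (for spectra:
    the longer wavelength).  At an edge, or when the local curvature is not
    concave, the grid maximum itself is returned.  Handles nonuniform grids.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be matching one-dimensional arrays")
    peak = np.flatnonzero(y == y.max())[-1]
    if peak == 0 or peak == y.size - 1:
        return float(x[peak])
    xs = x[peak - 1 : peak + 2]
    ys = y[peak - 1 : peak + 2]
    # quadratic through three points; vertex at -b / 2a
    a, b, _ = np.polyfit(xs - xs[1], ys, 2)
    if a >= 0:
        return float(x[peak])
    vertex = -b / (2.0 * a) + xs[1]
    # keep the vertex inside the bracketing interval
    return float(np.clip(vertex, xs[0], xs[2]))


def robust_noise_rms(y: np.ndarray) -> float:
    """Noise-floor estimate from the median absolute second difference.

    For iid Gaussian noise the second difference has variance 6 sigma^2, so
    sigma ~= 1.4826 * MAD(d2y) / sqrt(6).  Assumes the deterministic part of
    ``y`` is smooth on the sampling scale (near-uniform, dense grids).
    """
    y = np.asarray(y, dtype=float)
    if y.size < 4:
        return 0.0
    d2 = np.diff(y, n=2)
    return float(1.4826 * np.median(np.abs(d2)) / np.sqrt(6.0))
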