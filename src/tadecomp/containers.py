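"""Core data containers for transient-absorption (TA) analysis.

All pipeline stages exchange three immutable objects:

``TAMap``
    the pump-probe surface ΔOD(λ, t) with its wavelength and delay axes,
``Spectrum``
    a 1-D (Δ)OD slice on a wavelength axis (steady-state absorption,
    long-delay difference spectra, ΔΔOD spectra),
``Trace``
    a 1-D ΔOD kinetic trace on a delay axis, carrying the probe window
    it was averaged over in ``meta``.

Units are fixed throughout the package: wavelengths in nm, delays in ps,
signals in OD.  Unit conversions (mOD, fs, cm⁻¹) happen inside operations,
never inside containers or files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectralAxis",
    "DelayAxis",
    "TAMap",
    "Spectrum",
    "Trace",
]


def _as_1d_float(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got ndim={arr.ndim}")
    if arr.size < 2:
        raise ValueError(f"{name} needs at least two samples, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True, eq=False)
class SpectralAxis:
    """Probe wavelength axis in nm; strictly ascending, all positive."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_1d_float(self.wavelengths, "wavelength axis")
        if np.any(arr <= 0):
            raise ValueError("wavelength axis must be strictly positive (nm)")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("wavelength axis must be strictly ascending")
        arr.setflags(write=False)
        object.__setattr__(self, "wavelengths", arr)

    def __len__(self) -> int:
        return self.wavelengths.size

    @property
    def lo(self) -> float:
        return float(self.wavelengths[0])

    @property
    def hi(self) -> float:
        return float(self.wavelengths[-1])

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of samples with lo <= λ <= hi."""
        w = self.wavelengths
        return (w >= lo) & (w <= hi)

    def nearest_index(self, wavelength: float) -> int:
        return int(np.argmin(np.abs(self.wavelengths - wavelength)))


@dataclass(frozen=True, eq=False)
class DelayAxis:
    """Pump-probe delay axis in ps; strictly ascending, first delay >= 0.

    May be nonuniform -- the conventional acquisition axis is a linear
    segment through the sub-ps dynamics followed by log-spaced delays.
    """

    delays: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_1d_float(self.delays, "delay axis")
        if arr[0] < 0:
            raise ValueError("delay axis must start at a non-negative delay (ps)")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("delay axis must be strictly ascending")
        arr.setflags(write=False)
        object.__setattr__(self, "delays", arr)

    def __len__(self) -> int:
        return self.delays.size

    def window_mask(self, t_min: float, t_max: float = np.inf) -> np.ndarray:
        t = self.delays
        return (t >= t_min) & (t <= t_max)


def _same_axis(a: np.ndarray, b: np.ndarray) -> bool:
    return a.shape == b.shape and np.array_equal(a, b)


@dataclass(frozen=True, eq=False)
class TAMap:
    """A ΔOD(λ, t) surface: shape (n_delays, n_wavelengths), all finite."""

    saxis: SpectralAxis
    taxis: DelayAxis
    dod: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.dod, dtype=float)
        expected = (len(self.taxis), len(self.saxis))
        if arr.shape != expected:
            raise ValueError(
                f"dod shape {arr.shape} inconsistent with axes {expected} "
                "(rows = delays, columns = wavelengths)"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("dod contains non-finite values")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "dod", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dod.shape

    def spectrum_at(self, delay_index: int) -> "Spectrum":
        """The ΔOD spectrum at one delay index."""
        n = len(self.taxis)
        if not -n <= delay_index < n:
            raise IndexError(f"delay index {delay_index} out of range for {n} delays")
        return Spectrum(self.saxis, self.dod[delay_index])

    def share_axes_with(self, other: "TAMap") -> bool:
        return _same_axis(self.saxis.wavelengths, other.saxis.wavelengths) and _same_axis(
            self.taxis.delays, other.taxis.delays
        )

    def require_shared_axes(self, other: "TAMap") -> None:
        if not self.share_axes_with(other):
            raise ValueError("TA maps do not share wavelength/delay axes")


@dataclass(frozen=True, eq=False)
class Spectrum:
    """A 1-D (Δ)OD spectrum on a wavelength axis."""

    saxis: SpectralAxis
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (len(self.saxis),):
            raise ValueError(
                f"spectrum length {arr.shape} does not match axis length {len(self.saxis)}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("spectrum contains non-finite values")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return len(self.saxis)


@dataclass(frozen=True, eq=False)
class Trace:
    """A 1-D ΔOD kinetic trace on a delay axis.

    ``meta`` records how the trace was obtained, conventionally the probe
    window as ``center_nm`` and ``bandwidth_nm``.
    """

    taxis: DelayAxis
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (len(self.taxis),):
            raise ValueError(
                f"trace length {arr.shape} does not match axis length {len(self.taxis)}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("trace contains non-finite values")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @property
    def delays(self) -> np.ndarray:
        return self.taxis.delays

    def __len__(self) -> int:
        return len(self.taxis)
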