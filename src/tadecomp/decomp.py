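"""Pure-species isolation from mixed transient-absorption data.

A dark-adapted (or actinically prepared) sample is a mixture of species
excited with equal probability when pumped at their isosbestic point; its
TA map is then a weighted sum of pure-species maps.  This module infers
the mixing/subtraction factor ``c`` by four independent population
markers and removes the known species:

* **ddod** — dynamic difference spectra ΔΔOD = ΔOD(t+Δt) − ΔOD(t) cancel
  every static (product/bleach) contribution; once the short-lived
  species' excited state is extinct, the mixture's ΔΔOD equals ``c``
  times the pure species' ΔΔOD in excited-state-dominated windows.
* **oscillation** — the amplitude of coherent wave-packet modulation near
  520 nm, a signature carried exclusively by the resting-state species.
* **nir_se** — the NIR stimulated-emission amplitude, an exclusive
  measure of S1 population.
* **late_spectrum** — proportionality of time-averaged spectra at long
  delays.

All factors are closed-form linear least squares,
c = ⟨mix, pure⟩ / ⟨pure, pure⟩, on the respective marker signal.
Steady-state absorption decomposition (extracting the minor isomer's
absorption spectrum from dark- and light-adapted spectra given their
composition) completes the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .containers import Spectrum, TAMap
from . import kinetics
from .utils import parabolic_peak, robust_noise_rms

__all__ = [
    "ScaleMethod",
    "ScaleEstimate",
    "IsomerComposition",
    "DDoDSet",
    "DecomposedAbsorption",
    "DEFAULT_EXCITED_STATE_MASK",
    "dynamic_difference",
    "consecutive_pairs",
    "anchored_pairs",
    "estimate_scale_factor_ddod",
    "subtract_species",
    "estimate_factor_from_oscillations",
    "estimate_factor_from_se",
    "late_spectrum_match",
    "decompose_absorption",
]

#: spectral windows (nm) dominated by excited-state signal: the ESA band to
#: the blue of the bleach plus the NIR stimulated-emission band
DEFAULT_EXCITED_STATE_MASK = ((440.0, 500.0), (850.0, 1400.0))

#: delay (ps) beyond which the fast isomer's excited-state signal is extinct
DEFAULT_T_MIN = 0.6


class ScaleMethod(str, Enum):
    DDOD = "ddod"
    OSCILLATION = "oscillation"
    NIR_SE = "nir_se"
    LATE_SPECTRUM = "late_spectrum"


@dataclass(frozen=True)
class ScaleEstimate:
    """An inferred mixing/subtraction factor with its uncertainty.

    ``window`` records the delay window and spectral selection the
    estimate used; ``residual_norm`` is the root-sum-square misfit of
    mix − c·pure on the marker signal.
    """

    factor: float
    stderr: float
    residual_norm: float
    method: ScaleMethod
    window: dict

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError("stderr must be non-negative")

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "stderr": self.stderr,
            "residual_norm": self.residual_norm,
            "method": self.method.value,
            "window": self.window,
        }


@dataclass(frozen=True)
class IsomerComposition:
    """Ground-state fractions of the two co-resident isomers."""

    x_13c: float
    x_at: float

    def __post_init__(self) -> None:
        for name, x in (("x_13c", self.x_13c), ("x_at", self.x_at)):
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {x}")
        if abs(self.x_13c + self.x_at - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    @classmethod
    def from_at_fraction(cls, x_at: float) -> "IsomerComposition":
        return cls(x_13c=1.0 - x_at, x_at=x_at)


@dataclass(frozen=True)
class DDoDSet:
    """Dynamic difference spectra: entries (t_early, t_late, ΔΔOD)."""

    entries: tuple[tuple[float, float, Spectrum], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        for t1, t2, _ in self.entries:
            if t2 <= t1:
                raise ValueError(f"pair ({t1}, {t2}): second delay must exceed first")

    def __len__(self) -> int:
        return len(self.entries)

    def stack(self) -> np.ndarray:
        """All ΔΔOD spectra as a (n_pairs, n_wavelengths) array."""
        return np.array([s.values for _, _, s in self.entries])


# ---------------------------------------------------------------------------
# dynamic difference spectra

def dynamic_difference(tamap: TAMap, pairs) -> DDoDSet:
    """ΔΔOD spectra for the given (earlier, later) delay-index pairs."""
    n = len(tamap.taxis)
    entries = []
    for i, j in pairs:
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"delay index pair ({i}, {j}) out of range for {n} delays")
        if j <= i:
            raise ValueError(f"pair ({i}, {j}): second index must exceed first")
        spec = Spectrum(tamap.saxis, tamap.dod[j] - tamap.dod[i])
        entries.append((float(tamap.taxis.delays[i]), float(tamap.taxis.delays[j]), spec))
    return DDoDSet(tuple(entries))


def consecutive_pairs(tamap: TAMap, t_min: float) -> list[tuple[int, int]]:
    """Consecutive delay-index pairs whose earlier delay is >= t_min."""
    t = tamap.taxis.delays
    if t_min > t[-1]:
        raise ValueError(f"t_min = {t_min:g} ps exceeds the delay range (max {t[-1]:g} ps)")
    return [(i, i + 1) for i in range(len(t) - 1) if t[i] >= t_min]


def anchored_pairs(tamap: TAMap, t_min: float) -> list[tuple[int, int]]:
    """Delay pairs (t, t_last) for every t >= t_min before the final delay.

    Differencing each delay against a late anchor — by which all excited
    population has decayed — measures the remaining excited-state
    *amplitude* at t rather than its local derivative.  This mirrors the
    stage-spanning dynamic differences used in practice and suppresses a
    fast co-resident species by its amplitude ratio instead of the larger
    derivative ratio.
    """
    t = tamap.taxis.delays
    if t_min > t[-1]:
        raise ValueError(f"t_min = {t_min:g} ps exceeds the delay range (max {t[-1]:g} ps)")
    last = len(t) - 1
    return [(i, last) for i in range(last) if t[i] >= t_min]


def _mask_columns(tamap: TAMap, mask) -> np.ndarray:
    windows = list(mask)
    if not windows:
        raise ValueError("spectral mask must contain at least one window")
    sel = np.zeros(len(tamap.saxis), dtype=bool)
    for lo, hi in windows:
        sel |= tamap.saxis.window_mask(lo, hi)
    if not sel.any():
        raise ValueError(f"spectral mask {windows} selects no wavelengths")
    return sel


def _ls_factor(mix: np.ndarray, pure: np.ndarray) -> tuple[float, float, float]:
    """Closed-form least squares of mix ≈ c·pure.

    Returns (c, stderr, residual_norm); stderr is the textbook
    residual-variance formula sqrt(RSS/(N-1) / ⟨pure,pure⟩).
    """
    mix = np.asarray(mix, dtype=float).ravel()
    pure = np.asarray(pure, dtype=float).ravel()
    den = float(pure @ pure)
    if den == 0.0:
        raise ValueError("factor unidentifiable: pure signal is identically zero")
    c = float(mix @ pure) / den
    resid = mix - c * pure
    rss = float(resid @ resid)
    dof = max(mix.size - 1, 1)
    stderr = float(np.sqrt(rss / dof / den))
    return c, stderr, float(np.sqrt(rss))


def estimate_scale_factor_ddod(
    mix: TAMap,
    pure: TAMap,
    t_min: float = DEFAULT_T_MIN,
    mask=DEFAULT_EXCITED_STATE_MASK,
    pairs=None,
) -> ScaleEstimate:
    """Mixing factor from the convergence of dynamic difference spectra.

    Minimises sum over pairs (t >= t_min) and masked wavelengths of
    (ΔΔOD_mix − c ΔΔOD_pure)²; solved in closed form.  The standard error
    is a delete-one-pair jackknife.  Default pairs difference each delay
    >= t_min against the final delay (see :func:`anchored_pairs`); pass
    ``pairs`` explicitly for consecutive or staged differences.
    """
    mix.require_shared_axes(pure)
    cols = _mask_columns(mix, mask)
    if pairs is None:
        pairs = anchored_pairs(mix, t_min)
    if not pairs:
        raise ValueError(f"no delay pairs at t >= {t_min:g} ps")

    dmix = dynamic_difference(mix, pairs).stack()[:, cols]
    dpure = dynamic_difference(pure, pairs).stack()[:, cols]

    den = float(np.sum(dpure * dpure))
    if den == 0.0:
        raise ValueError(
            "factor unidentifiable: pure ΔΔOD is identically zero on the mask"
        )
    num = float(np.sum(dmix * dpure))
    c = num / den

    # delete-one-pair jackknife
    num_rows = np.sum(dmix * dpure, axis=1)
    den_rows = np.sum(dpure * dpure, axis=1)
    m = len(pairs)
    if m > 1:
        loo = np.full(m, np.nan)
        for k in range(m):
            d = den - den_rows[k]
            loo[k] = (num - num_rows[k]) / d if d > 0 else c
        stderr = float(np.sqrt((m - 1) / m * np.sum((loo - loo.mean()) ** 2)))
    else:
        stderr = 0.0

    resid_norm = float(np.sqrt(np.sum((dmix - c * dpure) ** 2)))
    return ScaleEstimate(
        factor=c,
        stderr=stderr,
        residual_norm=resid_norm,
        method=ScaleMethod.DDOD,
        window={"t_min_ps": float(t_min), "mask_nm": [list(w) for w in mask], "n_pairs": m},
    )


# ---------------------------------------------------------------------------
# subtraction

def subtract_species(mix: TAMap, pure: TAMap, c: float) -> TAMap:
    """Pixelwise mix − c·pure: removes the known species' weighted map."""
    mix.require_shared_axes(pure)
    if c < 0:
        raise ValueError("subtraction factor must be non-negative")
    return TAMap(mix.saxis, mix.taxis, mix.dod - c * pure.dod)


# ---------------------------------------------------------------------------
# coherence (oscillation-amplitude) marker

def _has_vibrational_peak(residual, wn_min: float = 60.0, height_factor: float = 10.0) -> bool:
    """True if the residual's power spectrum shows an isolated interior
    peak above ``wn_min`` cm^-1 standing ``height_factor`` times over the
    median power — the signature of a coherent mode, absent from both
    white noise and smooth fit misfit."""
    from scipy.signal import find_peaks

    ps = kinetics.power_spectrum(residual)
    sel = ps.wavenumbers >= wn_min
    power = ps.power[sel]
    if power.size < 8 or power.max() <= 0.0:
        return False
    peaks, _ = find_peaks(power)
    if peaks.size == 0:
        return False
    return bool(power[peaks].max() > height_factor * np.median(power))


def estimate_factor_from_oscillations(
    mix: TAMap,
    pure: TAMap,
    window_center: float = 520.0,
    window_width: float = 20.0,
    t_range: tuple[float, float] = (kinetics.ARTIFACT_WINDOW_PS, 3.0),
    n_exp: int = 2,
    n_exp_pure: int | None = None,
    min_kinetic_tau: float = 0.2,
) -> ScaleEstimate:
    """Mixing factor from coherent wave-packet modulation amplitudes.

    Band-averaged traces at the oscillation window (default ~520 nm) are
    stripped of their population kinetics (``n_exp``-exponential fit);
    the factor is the least-squares scaling of the pure species'
    oscillatory residual onto the mixture's.  Valid when the coherence is
    exclusively a pure-species signature.

    ``n_exp`` applies to the mixture trace and, unless ``n_exp_pure`` is
    given, to the pure trace as well.  ``min_kinetic_tau`` floors the
    fitted population lifetimes: a kinetic component faster than the
    vibrational period is indistinguishable from the coherence itself and
    would chase oscillation lobes, so the floor should sit near the
    slowest oscillation period of interest (default 0.2 ps ~ a 170 cm^-1
    mode).
    """
    mix.require_shared_axes(pure)
    t_lo, t_hi = t_range
    if t_hi <= t_lo:
        raise ValueError("t_range must be an increasing (t_lo, t_hi) pair")
    if n_exp_pure is None:
        n_exp_pure = n_exp

    def residual_of(tamap: TAMap, order: int):
        trace = kinetics.extract_trace(tamap, window_center, window_width)
        sel = trace.taxis.window_mask(t_lo, t_hi)
        if sel.sum() < 3 * order + 2:
            raise ValueError(f"too few delays inside t_range {t_range}")
        from .containers import DelayAxis, Trace

        sub = Trace(DelayAxis(trace.delays[sel]), trace.values[sel], meta=trace.meta)
        fit = kinetics.fit_multiexp(
            sub,
            order,
            t_start=float(sub.delays[0]),
            tau_bounds=(min_kinetic_tau, kinetics.TAU_BOUNDS[1]),
        )
        return kinetics.isolate_oscillations(sub, fit)

    res_pure = residual_of(pure, n_exp_pure)
    res_mix = residual_of(mix, n_exp)
    r_pure = res_pure.values
    r_mix = res_mix.values

    floor = robust_noise_rms(r_pure)
    rms = float(np.sqrt(np.mean(r_pure**2)))
    if rms == 0.0 or rms < 3.0 * floor or not _has_vibrational_peak(res_pure):
        raise ValueError(
            "no coherence marker: pure-species residual at "
            f"{window_center:g} nm (rms {rms:.3g} OD, noise floor "
            f"{floor:.3g} OD) carries no resolvable vibrational peak"
        )

    c, stderr, resid_norm = _ls_factor(r_mix, r_pure)
    return ScaleEstimate(
        factor=c,
        stderr=stderr,
        residual_norm=resid_norm,
        method=ScaleMethod.OSCILLATION,
        window={
            "center_nm": window_center,
            "width_nm": window_width,
            "t_range_ps": list(t_range),
            "n_exp": n_exp,
            "n_exp_pure": n_exp_pure,
        },
    )


# ---------------------------------------------------------------------------
# NIR stimulated-emission marker

def estimate_factor_from_se(
    mix: TAMap,
    pure: TAMap,
    nir_window: tuple[float, float] = (900.0, 1400.0),
    t_range: tuple[float, float] = (DEFAULT_T_MIN, 5.0),
) -> ScaleEstimate:
    """Mixing factor from NIR stimulated-emission amplitudes (an exclusive
    S1-population measure), as the closed-form least-squares scaling of the
    pure map onto the mixture inside window × t_range."""
    mix.require_shared_axes(pure)
    cols = _mask_columns(mix, [nir_window])
    rows = mix.taxis.window_mask(*t_range)
    if not rows.any():
        raise ValueError(f"no delays inside t_range {t_range}")

    sub_mix = mix.dod[np.ix_(rows, cols)]
    sub_pure = pure.dod[np.ix_(rows, cols)]
    c, stderr, resid_norm = _ls_factor(sub_mix, sub_pure)
    return ScaleEstimate(
        factor=c,
        stderr=stderr,
        residual_norm=resid_norm,
        method=ScaleMethod.NIR_SE,
        window={"nir_window_nm": list(nir_window), "t_range_ps": list(t_range)},
    )


# ---------------------------------------------------------------------------
# late-spectrum proportionality

def late_spectrum_match(map_a: TAMap, map_b: TAMap, t_min: float) -> ScaleEstimate:
    """Scalar factor c with c·(late spectrum of B) ≈ late spectrum of A,
    where each late spectrum is the time average over delays >= t_min."""
    map_a.require_shared_axes(map_b)
    rows = map_a.taxis.delays >= t_min
    if not rows.any():
        raise ValueError(f"no delays at t >= {t_min:g} ps")
    spec_a = map_a.dod[rows].mean(axis=0)
    spec_b = map_b.dod[rows].mean(axis=0)
    c, stderr, resid_norm = _ls_factor(spec_a, spec_b)
    return ScaleEstimate(
        factor=c,
        stderr=stderr,
        residual_norm=resid_norm,
        method=ScaleMethod.LATE_SPECTRUM,
        window={"t_min_ps": float(t_min), "n_delays": int(rows.sum())},
    )


# ---------------------------------------------------------------------------
# steady-state absorption decomposition

@dataclass(frozen=True)
class DecomposedAbsorption:
    """Extracted minor-isomer absorption spectrum and its band maximum."""

    spectrum: Spectrum
    lambda_max_nm: float


def decompose_absorption(
    a_da: Spectrum, a_la: Spectrum, comp: IsomerComposition
) -> DecomposedAbsorption:
    """Extract the 13-cis absorption spectrum from dark-adapted (mixture)
    and light-adapted (pure all-trans) spectra:

        A_13C(λ) = (A_DA(λ) − x_AT · A_LA(λ)) / x_13C.

    λmax is refined by 3-point parabolic interpolation around the grid
    peak (ties broken toward the longer wavelength).  Negative dips are
    reported as-is — clipping would bias λmax — but flagged with a
    warning.
    """
    if not np.array_equal(a_da.saxis.wavelengths, a_la.saxis.wavelengths):
        raise ValueError("spectra must share the wavelength axis")
    if comp.x_13c == 0.0:
        raise ValueError("x_13c = 0: the 13C spectrum is unidentifiable")
    values = (a_da.values - comp.x_at * a_la.values) / comp.x_13c
    peak = float(values.max())
    if peak > 0 and values.min() < -1e-9 * peak:
        warnings.warn(
            "decomposed spectrum has negative dips; the assumed composition "
            "or the purity of the light-adapted reference may be off",
            stacklevel=2,
        )
    lam_max = parabolic_peak(a_da.saxis.wavelengths, values)
    return DecomposedAbsorption(Spectrum(a_da.saxis, values), lam_max)
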