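"""Kinetic-trace analysis: extraction, multi-exponential fitting,
coherent-oscillation isolation, and pump-probe anisotropy.

Multi-exponential fits use variable projection: for any candidate set of
lifetimes the amplitudes (and offset) are a linear least-squares
sub-problem, so the nonlinear search runs over the lifetimes alone, in
log space, with a multistart grid to cope with the local minima that
nonuniform (linear + log-spaced) delay axes create.

Coherent vibrational wave-packet modulations are isolated by subtracting
the multi-exponential fit of the population kinetics from the trace; the
first 80 fs are excluded (coherent-artifact window of finite pump/probe
pulses).  The oscillatory residual is then characterised either by an FFT
power spectrum on a cm^-1 axis or by damped-cosine least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .containers import DelayAxis, TAMap, Trace
from .utils import C_CM_PER_PS

__all__ = [
    "KineticFit",
    "FittedOscillation",
    "OscFit",
    "PowerSpectrum",
    "AnisotropyResult",
    "extract_trace",
    "fit_multiexp",
    "isolate_oscillations",
    "power_spectrum",
    "fit_oscillations",
    "anisotropy",
]

#: coherent-artifact window: data before 80 fs carry pulse-overlap signatures
ARTIFACT_WINDOW_PS = 0.08

TAU_BOUNDS = (0.01, 1000.0)
_MULTISTART_RANGE = (0.05, 200.0)
_N_STARTS = 8


# ---------------------------------------------------------------------------
# trace extraction

def extract_trace(tamap: TAMap, center: float, bandwidth: float) -> Trace:
    """Band-averaged kinetic trace: unweighted mean of ΔOD over the probe
    wavelengths within center ± bandwidth/2.

    If the window is narrower than the grid spacing the nearest single
    pixel is used (with a warning).  A window that misses the axis
    entirely is an error.
    """
    if bandwidth < 0:
        raise ValueError("bandwidth must be non-negative")
    lam = tamap.saxis.wavelengths
    lo, hi = center - bandwidth / 2.0, center + bandwidth / 2.0
    if hi < lam[0] or lo > lam[-1]:
        raise ValueError(
            f"probe window [{lo:g}, {hi:g}] nm does not intersect the "
            f"wavelength axis [{lam[0]:g}, {lam[-1]:g}] nm"
        )
    mask = (lam >= lo) & (lam <= hi)
    if not mask.any():
        idx = tamap.saxis.nearest_index(center)
        warnings.warn(
            f"probe window [{lo:g}, {hi:g}] nm is narrower than the grid "
            f"spacing; using the single pixel at {lam[idx]:g} nm",
            stacklevel=2,
        )
        mask = np.zeros_like(mask)
        mask[idx] = True
    values = tamap.dod[:, mask].mean(axis=1)
    return Trace(
        tamap.taxis,
        values,
        meta={"center_nm": float(center), "bandwidth_nm": float(bandwidth)},
    )


# ---------------------------------------------------------------------------
# multi-exponential fitting

@dataclass(frozen=True)
class KineticFit:
    """Result of offset + sum_i A_i exp(-t/tau_i) fitted on t >= t_start.

    Lifetimes are reported sorted ascending with their amplitudes aligned.
    ``amplitude_stderr``/``tau_stderr``/``offset_stderr`` come from the
    Gauss-Newton covariance of the full nonlinear problem.
    """

    amplitudes: np.ndarray
    taus: np.ndarray
    offset: float
    t_start: float
    rss: float
    amplitude_stderr: np.ndarray
    tau_stderr: np.ndarray
    offset_stderr: float
    n_points: int

    def __post_init__(self) -> None:
        taus = np.asarray(self.taus, dtype=float)
        if np.any(taus <= 0) or np.any(np.diff(taus) <= 0):
            raise ValueError("taus must be strictly positive and strictly ascending")
        if len(self.amplitudes) != len(taus):
            raise ValueError("amplitudes and taus must have equal length")

    @property
    def n_exp(self) -> int:
        return len(self.taus)

    def model(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.offset)
        for a, tau in zip(self.amplitudes, self.taus):
            out = out + a * np.exp(-t / tau)
        return out

    @property
    def amplitude_ratio(self) -> tuple[float, float]:
        """(A_fast / A_slow, stderr) for a biexponential fit.

        Reported as a ratio with propagated uncertainty so "equal
        amplitudes" can be asserted as |ratio - 1| within tolerance.
        """
        if self.n_exp != 2:
            raise ValueError("amplitude_ratio is defined for biexponential fits")
        a1, a2 = self.amplitudes
        s1, s2 = self.amplitude_stderr
        ratio = a1 / a2
        stderr = abs(ratio) * np.hypot(
            s1 / a1 if a1 != 0 else 0.0, s2 / a2 if a2 != 0 else 0.0
        )
        return float(ratio), float(stderr)


def _design_matrix(t: np.ndarray, taus: np.ndarray, with_offset: bool) -> np.ndarray:
    cols = [np.exp(-t / tau) for tau in taus]
    if with_offset:
        cols.append(np.ones_like(t))
    return np.column_stack(cols)


def _project(t, y, taus, with_offset):
    """Solve the linear amplitudes for fixed lifetimes; return (coef, residual)."""
    design = _design_matrix(t, taus, with_offset)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef, y - design @ coef


def _start_grids(n: int, tau_bounds: tuple[float, float]) -> list[np.ndarray]:
    """Log-spaced lifetime seed grids spanning the multistart range."""
    lo = max(_MULTISTART_RANGE[0], tau_bounds[0] * 1.01)
    hi = min(_MULTISTART_RANGE[1], tau_bounds[1] * 0.99)
    if hi <= lo:
        lo, hi = tau_bounds[0] * 1.01, tau_bounds[1] * 0.99
    starts = [np.geomspace(lo, hi, n)] if n > 1 else []
    n_centers = _N_STARTS - len(starts)
    for center in np.geomspace(lo, hi, n_centers):
        spread = np.geomspace(0.4, 2.5, n) if n > 1 else np.array([1.0])
        starts.append(np.clip(center * spread, lo, hi))
    return starts


def fit_multiexp(
    trace: Trace,
    n: int,
    t_start: float = ARTIFACT_WINDOW_PS,
    with_offset: bool = True,
    tau_bounds: tuple[float, float] = TAU_BOUNDS,
) -> KineticFit:
    """Least-squares multi-exponential fit of a kinetic trace on t >= t_start.

    Variable projection over log-lifetimes with a multistart seed grid;
    the best converged start is returned with lifetimes sorted ascending.
    Lifetimes are bounded to ``tau_bounds`` (default [0.01, 1000] ps;
    raise the lower bound above the vibrational period when the residual
    will be used for coherence analysis, so no component can chase an
    oscillation lobe); a solution pinned at a bound triggers a warning,
    and failure of every start raises with the best residual attached.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < tau_bounds[0] < tau_bounds[1]:
        raise ValueError("tau_bounds must be an increasing positive pair")
    mask = trace.delays >= t_start
    t = trace.delays[mask]
    y = trace.values[mask]
    min_points = 3 * n + 2
    if t.size < min_points:
        raise ValueError(
            f"need at least {min_points} points at t >= {t_start:g} ps, have {t.size}"
        )

    log_bounds = (np.log(tau_bounds[0]), np.log(tau_bounds[1]))

    def residual(log_taus: np.ndarray) -> np.ndarray:
        _, resid = _project(t, y, np.exp(log_taus), with_offset)
        return resid

    best = None
    for tau0 in _start_grids(n, tau_bounds):
        result = least_squares(
            residual,
            x0=np.log(tau0),
            bounds=log_bounds,
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if not result.success:
            continue
        if best is None or result.cost < best.cost:
            best = result
    if best is None:
        raise RuntimeError(
            f"multi-exponential fit failed to converge from any of "
            f"{_N_STARTS} starts (n={n}, {t.size} points)"
        )

    taus = np.exp(best.x)
    order = np.argsort(taus)
    taus = taus[order]
    if np.any(taus <= tau_bounds[0] * 1.001) or np.any(taus >= tau_bounds[1] * 0.999):
        warnings.warn(
            f"fitted lifetime at the search bound {tau_bounds} ps; "
            "the model order or fit window is likely wrong",
            stacklevel=2,
        )
    coef, resid = _project(t, y, taus, with_offset)
    amplitudes = coef[:n]
    offset = float(coef[n]) if with_offset else 0.0
    rss = float(resid @ resid)

    amp_err, tau_err, off_err = _stderr(t, amplitudes, taus, offset, with_offset, rss)
    return KineticFit(
        amplitudes=amplitudes,
        taus=taus,
        offset=offset,
        t_start=float(t_start),
        rss=rss,
        amplitude_stderr=amp_err,
        tau_stderr=tau_err,
        offset_stderr=off_err,
        n_points=int(t.size),
    )


def _stderr(t, amplitudes, taus, offset, with_offset, rss):
    """Per-parameter standard errors from the full-model Jacobian."""
    n = len(taus)
    cols = []
    for a, tau in zip(amplitudes, taus):
        decay = np.exp(-t / tau)
        cols.append(decay)  # d/dA
        cols.append(a * t / tau**2 * decay)  # d/dtau
    if with_offset:
        cols.append(np.ones_like(t))
    jac = np.column_stack(cols)
    dof = max(t.size - jac.shape[1], 1)
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.pinv(jac.T @ jac)
    diag = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    amp_err = diag[0 : 2 * n : 2]
    tau_err = diag[1 : 2 * n : 2]
    off_err = float(diag[-1]) if with_offset else 0.0
    return amp_err, tau_err, off_err


# ---------------------------------------------------------------------------
# oscillation residuals

def isolate_oscillations(trace: Trace, fit: KineticFit) -> Trace:
    """Oscillatory residual: trace minus its multi-exponential fit,
    restricted to t >= max(fit.t_start, 80 fs)."""
    t_min = max(fit.t_start, ARTIFACT_WINDOW_PS)
    mask = trace.delays >= t_min
    if not mask.any():
        raise ValueError(
            f"no post-artifact window: all delays are below {t_min:g} ps"
        )
    t = trace.delays[mask]
    resid = trace.values[mask] - fit.model(t)
    meta = dict(trace.meta)
    meta["kind"] = "oscillation_residual"
    return Trace(DelayAxis(t), resid, meta=meta)


@dataclass(frozen=True)
class PowerSpectrum:
    """FFT power of an oscillatory residual on a wavenumber (cm^-1) axis."""

    wavenumbers: np.ndarray
    power: np.ndarray

    @property
    def bin_width(self) -> float:
        return float(self.wavenumbers[1] - self.wavenumbers[0])

    def peak_wavenumber(self) -> float:
        return float(self.wavenumbers[np.argmax(self.power)])


def _resample_uniform(trace: Trace) -> tuple[np.ndarray, np.ndarray, float]:
    """Linear-interpolate a trace onto a uniform grid at the minimum native
    spacing (introduces a small low-pass bias on log-spaced tails)."""
    t = trace.delays
    dt = float(np.min(np.diff(t)))
    tu = np.arange(t[0], t[-1] + dt / 2, dt)
    yu = np.interp(tu, t, trace.values)
    return tu, yu, dt


def power_spectrum(residual: Trace) -> PowerSpectrum:
    """One-sided FFT power spectrum of an oscillatory residual, reported
    against vibrational wavenumber ν̃ = f / c (cm^-1)."""
    tu, yu, dt = _resample_uniform(residual)
    yu = yu - yu.mean()
    spectrum = np.fft.rfft(yu)
    freq = np.fft.rfftfreq(tu.size, dt)  # 1/ps
    power = np.abs(spectrum) ** 2 / tu.size**2
    return PowerSpectrum(freq / C_CM_PER_PS, power)


@dataclass(frozen=True)
class FittedOscillation:
    """One damped cosine a exp(-t/d) cos(2π c ν̃ t + φ) recovered from a
    residual; amplitude is in OD (unlike the generator's relative
    modulation depth)."""

    wavenumber: float
    damping_tau: float
    phase: float
    amplitude: float


@dataclass(frozen=True)
class OscFit:
    """Damped-cosine decomposition of an oscillatory residual."""

    components: tuple[FittedOscillation, ...]
    rss: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        wn = [c.wavenumber for c in self.components]
        if any(w <= 0 for w in wn) or any(np.diff(wn) <= 0):
            raise ValueError("component wavenumbers must be positive and ascending")

    def model(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for c in self.components:
            omega = 2.0 * np.pi * C_CM_PER_PS * c.wavenumber
            out += c.amplitude * np.exp(-t / c.damping_tau) * np.cos(omega * t + c.phase)
        return out


def fit_oscillations(residual: Trace, n_components: int = 1) -> OscFit:
    """Damped-cosine least squares on an oscillatory residual.

    Mode frequencies are seeded from the FFT power spectrum; if fewer
    resolvable peaks exist than requested, a warning is emitted and the
    resolvable ones are fitted (best effort).  An all-zero residual yields
    an empty fit.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    y = residual.values
    scale = float(np.max(np.abs(y))) if y.size else 0.0
    if scale == 0.0:
        return OscFit(components=(), rss=0.0)

    ps = power_spectrum(residual)
    peaks, props = find_peaks(ps.power, height=1e-6 * ps.power.max())
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(ps.power[1:])) + 1])
        props = {"peak_heights": ps.power[peaks]}
    order = np.argsort(props["peak_heights"])[::-1]
    seeds = ps.wavenumbers[peaks[order]][:n_components]
    if seeds.size < n_components:
        warnings.warn(
            f"requested {n_components} oscillation components but only "
            f"{seeds.size} resolvable spectral peaks; fitting {seeds.size}",
            stacklevel=2,
        )
    m = seeds.size

    t = residual.delays
    span = float(t[-1] - t[0])

    # parameters per component: amplitude, log-damping, phase, wavenumber
    x0 = np.concatenate(
        [[scale, np.log(max(span / 3.0, 0.05)), 0.0, wn] for wn in seeds]
    )
    lower = np.tile([-5.0 * scale, np.log(0.01), -2.0 * np.pi, 1.0], m)
    upper = np.tile([5.0 * scale, np.log(1e4), 2.0 * np.pi, 1.0e4], m)

    def model_of(x: np.ndarray) -> np.ndarray:
        out = np.zeros_like(t)
        for k in range(m):
            a, logd, phase, wn = x[4 * k : 4 * k + 4]
            omega = 2.0 * np.pi * C_CM_PER_PS * wn
            out += a * np.exp(-t / np.exp(logd)) * np.cos(omega * t + phase)
        return out

    result = least_squares(
        lambda x: model_of(x) - y,
        x0=x0,
        bounds=(lower, upper),
        method="trf",
        xtol=1e-13,
        ftol=1e-13,
    )

    comps = []
    for k in range(m):
        a, logd, phase, wn = result.x[4 * k : 4 * k + 4]
        if a < 0:  # canonical form: positive amplitude, phase shifted by pi
            a, phase = -a, phase + np.pi
        phase = float(np.arctan2(np.sin(phase), np.cos(phase)))
        comps.append(
            FittedOscillation(
                wavenumber=float(wn),
                damping_tau=float(np.exp(logd)),
                phase=phase,
                amplitude=float(a),
            )
        )
    comps.sort(key=lambda c: c.wavenumber)
    rss = float(result.fun @ result.fun)
    return OscFit(components=tuple(comps), rss=rss)


# ---------------------------------------------------------------------------
# anisotropy

@dataclass(frozen=True)
class AnisotropyResult:
    """r(t) = (ΔOD∥ - ΔOD⊥) / (ΔOD∥ + 2 ΔOD⊥) with the magic-angle signal
    (ΔOD∥ + 2 ΔOD⊥)/3.  Points whose denominator falls below the noise
    floor are masked out via ``valid`` (their r is set to 0, not NaN)."""

    r: Trace
    magic_angle: Trace
    valid: np.ndarray


def anisotropy(par: Trace, perp: Trace, noise_floor: float = 0.0) -> AnisotropyResult:
    """Pump-probe polarization anisotropy of two traces sharing a delay axis.

    r = 0.4 in the parallel-transition-dipole limit, 0 for isotropic
    signals, 1 when the perpendicular signal vanishes.
    """
    if not np.array_equal(par.delays, perp.delays):
        raise ValueError("parallel and perpendicular traces must share the delay axis")
    if noise_floor < 0:
        raise ValueError("noise_floor must be non-negative")
    denom = par.values + 2.0 * perp.values
    valid = np.abs(denom) > noise_floor
    r = np.zeros_like(denom)
    np.divide(par.values - perp.values, denom, out=r, where=valid)
    meta = {"quantity": "anisotropy"}
    return AnisotropyResult(
        r=Trace(par.taxis, r, meta=meta),
        magic_angle=Trace(par.taxis, denom / 3.0, meta={"quantity": "magic_angle"}),
        valid=valid,
    )
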