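"""Forward generator of synthetic absorption spectra and TA maps.

The generator emulates femtosecond pump-probe measurements on retinal
proteins whose signals are mixtures of independent species.  Each species
contributes excited-state absorption (ESA, positive ΔOD), stimulated
emission (SE, negative), ground-state bleach (GSB, negative) and a
photoproduct band (positive), tied together by a multi-exponential
excited-state survival probability

    P(t) = sum_i A_i exp(-t / tau_i),        sum_i A_i = 1,

an isomerization quantum yield ``phi`` that routes the decayed population
to the photoproduct, optional continuous ("ballistic") band shifting of
the ESA/SE centers, and optional low-frequency damped coherent
oscillations that modulate the excited-state signal inside a spectral
window:

    dOD(λ, t) = P(t) [σ_ESA(λ, t) - σ_SE(λ, t)] (1 + osc(λ, t))
                - P(t) σ_GS(λ)
                + phi (1 - P(t)) [σ_prod(λ) - σ_GS(λ)].

At t → ∞ the map converges to the long-delay difference spectrum
``phi (σ_prod - σ_GS)``; with phi = 0 the ground state recovers fully.

Everything downstream (scale-factor inference, kinetics, quantum-yield
estimation) is validated against the ground truth this module provides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .containers import DelayAxis, SpectralAxis, TAMap, Spectrum
from .utils import C_CM_PER_PS, NM_TO_WAVENUMBER

__all__ = [
    "Band",
    "ShiftModel",
    "KineticComponent",
    "OscComponent",
    "SpeciesSpec",
    "MixtureSpec",
    "spectral_axis",
    "linear_log_delay_axis",
    "uniform_delay_axis",
    "gen_absorption",
    "gen_species_map",
    "gen_mixture",
    "gen_double_pump",
    "band_wavenumber_integral",
    "band_for_dipole_ratio",
    "default_at_spec",
    "default_c13_spec",
    "default_k_spec",
]

#: generator axes must resolve band structure; shorter axes are refused
_MIN_AXIS_LEN = 8

_AMPLITUDE_SUM_TOL = 1e-8


# ---------------------------------------------------------------------------
# axis factories

def spectral_axis(lo: float = 430.0, hi: float = 1400.0, num: int = 120) -> SpectralAxis:
    """Uniform probe-wavelength axis in nm (default spans the broadband
    visible-to-NIR probe window, 430-1400 nm)."""
    if num < _MIN_AXIS_LEN:
        raise ValueError(f"spectral axis needs at least {_MIN_AXIS_LEN} samples")
    return SpectralAxis(np.linspace(lo, hi, num))


def linear_log_delay_axis(
    dt_linear: float = 0.02,
    t_linear: float = 0.5,
    t_max: float = 100.0,
    n_log: int = 50,
) -> DelayAxis:
    """Delay axis in ps: linear from 0 through ``t_linear`` (default the
    first 500 fs), then log-spaced out to ``t_max``.  This mirrors how
    pump-probe delay scans are conventionally acquired."""
    lin = np.arange(0.0, t_linear + dt_linear / 2, dt_linear)
    log = np.geomspace(t_linear, t_max, n_log + 1)[1:]
    axis = np.concatenate([lin, log])
    if axis.size < _MIN_AXIS_LEN:
        raise ValueError(f"delay axis needs at least {_MIN_AXIS_LEN} samples")
    return DelayAxis(axis)


def uniform_delay_axis(t_max: float = 3.0, dt: float = 0.01, t0: float = 0.0) -> DelayAxis:
    """Uniform delay grid, the acquisition mode for coherence-resolved scans
    (default 10 fs steps to 3 ps)."""
    axis = np.arange(t0, t_max + dt / 2, dt)
    if axis.size < _MIN_AXIS_LEN:
        raise ValueError(f"delay axis needs at least {_MIN_AXIS_LEN} samples")
    return DelayAxis(axis)


# ---------------------------------------------------------------------------
# generative species description

@dataclass(frozen=True)
class Band:
    """One Gaussian band in wavelength: center (nm), width (Gaussian sigma,
    nm) and a non-negative OD-scale amplitude (peak cross-section)."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be non-negative")

    def profile(self, wavelengths: np.ndarray, center: float | np.ndarray | None = None):
        c = self.center if center is None else center
        return self.amplitude * np.exp(-((wavelengths - c) ** 2) / (2.0 * self.width**2))

    def to_dict(self) -> dict:
        return {"center": self.center, "width": self.width, "amplitude": self.amplitude}

    @classmethod
    def from_dict(cls, d: dict) -> "Band":
        return cls(**d)


@dataclass(frozen=True)
class ShiftModel:
    """Exponential band-center trajectory, the signature of ballistic
    excited-state motion: center(t) = end + (start - end) exp(-t/tau)."""

    center_start: float
    center_end: float
    tau_shift: float

    def __post_init__(self) -> None:
        if self.tau_shift <= 0:
            raise ValueError("tau_shift must be positive")

    def offset(self, t: np.ndarray) -> np.ndarray:
        """Center displacement relative to ``center_start`` at delay t."""
        return (self.center_end - self.center_start) * (1.0 - np.exp(-t / self.tau_shift))

    def to_dict(self) -> dict:
        return {
            "center_start": self.center_start,
            "center_end": self.center_end,
            "tau_shift": self.tau_shift,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShiftModel":
        return cls(**d)


@dataclass(frozen=True)
class KineticComponent:
    """One term A exp(-t/tau) of the excited-state survival probability."""

    amplitude: float
    tau: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("kinetic amplitude must be non-negative")
        if self.tau <= 0:
            raise ValueError("kinetic tau must be positive")

    def to_dict(self) -> dict:
        return {"amplitude": self.amplitude, "tau": self.tau}

    @classmethod
    def from_dict(cls, d: dict) -> "KineticComponent":
        return cls(**d)


@dataclass(frozen=True)
class OscComponent:
    """A damped coherent oscillation modulating the excited-state signal.

    The modulation is multiplicative on the ESA-SE term and spectrally
    windowed by a unit-peak Gaussian g(λ) centered at ``window_center``:

        osc(λ, t) = rel_amplitude g(λ) exp(-t/damping_tau)
                    cos(2 π c ν̃ t + phase)

    with ν̃ the mode wavenumber in cm^-1 and c the speed of light in cm/ps.
    """

    wavenumber: float
    damping_tau: float
    phase: float
    rel_amplitude: float
    window_center: float
    window_width: float

    def __post_init__(self) -> None:
        if self.wavenumber <= 0:
            raise ValueError("oscillation wavenumber must be positive")
        if not 0.0 <= self.rel_amplitude <= 0.5:
            raise ValueError("rel_amplitude must lie in [0, 0.5]")
        if self.damping_tau <= 0:
            raise ValueError("damping_tau must be positive")
        if self.window_width <= 0:
            raise ValueError("window_width must be positive")

    def modulation(self, wavelengths: np.ndarray, t: np.ndarray) -> np.ndarray:
        g = np.exp(-((wavelengths - self.window_center) ** 2) / (2.0 * self.window_width**2))
        omega = 2.0 * np.pi * C_CM_PER_PS * self.wavenumber
        return self.rel_amplitude * g * np.exp(-t / self.damping_tau) * np.cos(
            omega * t + self.phase
        )

    def to_dict(self) -> dict:
        return {
            "wavenumber": self.wavenumber,
            "damping_tau": self.damping_tau,
            "phase": self.phase,
            "rel_amplitude": self.rel_amplitude,
            "window_center": self.window_center,
            "window_width": self.window_width,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OscComponent":
        return cls(**d)


@dataclass(frozen=True)
class SpeciesSpec:
    """Full generative description of one photoactive species."""

    gsb_band: Band
    esa_bands: tuple[Band, ...] = ()
    se_bands: tuple[Band, ...] = ()
    product_band: Band | None = None
    esa_shift: ShiftModel | None = None
    se_shift: ShiftModel | None = None
    kinetics: tuple[KineticComponent, ...] = (KineticComponent(1.0, 0.5),)
    phi_iso: float = 0.5
    oscillations: tuple[OscComponent, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "esa_bands", tuple(self.esa_bands))
        object.__setattr__(self, "se_bands", tuple(self.se_bands))
        object.__setattr__(self, "kinetics", tuple(self.kinetics))
        object.__setattr__(self, "oscillations", tuple(self.oscillations))
        if self.gsb_band.amplitude <= 0:
            raise ValueError("gsb_band amplitude must be positive")
        if not 0.0 <= self.phi_iso <= 1.0:
            raise ValueError("phi_iso must lie in [0, 1]")
        if not self.kinetics:
            raise ValueError("at least one kinetic component is required")
        total = sum(k.amplitude for k in self.kinetics)
        if abs(total - 1.0) > _AMPLITUDE_SUM_TOL:
            raise ValueError(
                f"kinetic amplitudes must sum to 1 (got {total!r})"
            )

    @property
    def max_tau(self) -> float:
        return max(k.tau for k in self.kinetics)

    def survival(self, t: np.ndarray) -> np.ndarray:
        """Excited-state survival probability P(t)."""
        t = np.asarray(t, dtype=float)
        return sum(k.amplitude * np.exp(-t / k.tau) for k in self.kinetics)

    def to_dict(self) -> dict:
        return {
            "gsb_band": self.gsb_band.to_dict(),
            "esa_bands": [b.to_dict() for b in self.esa_bands],
            "se_bands": [b.to_dict() for b in self.se_bands],
            "product_band": self.product_band.to_dict() if self.product_band else None,
            "esa_shift": self.esa_shift.to_dict() if self.esa_shift else None,
            "se_shift": self.se_shift.to_dict() if self.se_shift else None,
            "kinetics": [k.to_dict() for k in self.kinetics],
            "phi_iso": self.phi_iso,
            "oscillations": [o.to_dict() for o in self.oscillations],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpeciesSpec":
        return cls(
            gsb_band=Band.from_dict(d["gsb_band"]),
            esa_bands=tuple(Band.from_dict(b) for b in d.get("esa_bands", [])),
            se_bands=tuple(Band.from_dict(b) for b in d.get("se_bands", [])),
            product_band=Band.from_dict(d["product_band"]) if d.get("product_band") else None,
            esa_shift=ShiftModel.from_dict(d["esa_shift"]) if d.get("esa_shift") else None,
            se_shift=ShiftModel.from_dict(d["se_shift"]) if d.get("se_shift") else None,
            kinetics=tuple(KineticComponent.from_dict(k) for k in d["kinetics"]),
            phi_iso=d.get("phi_iso", 0.5),
            oscillations=tuple(OscComponent.from_dict(o) for o in d.get("oscillations", [])),
        )


@dataclass(frozen=True)
class MixtureSpec:
    """A weighted mixture of species plus iid Gaussian pixel noise.

    The weights are the excited-population fractions of the co-resident
    species (isosbestic-point pumping makes these equal to the ground-state
    fractions); they must be non-negative and sum to 1.
    """

    species: tuple[SpeciesSpec, ...]
    weights: tuple[float, ...]
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if len(self.species) != len(self.weights):
            raise ValueError(
                f"{len(self.weights)} weights for {len(self.species)} species"
            )
        if not self.species:
            raise ValueError("mixture needs at least one species")
        if any(w < 0 for w in self.weights):
            raise ValueError("mixture weights must be non-negative")
        if abs(sum(self.weights) - 1.0) > _AMPLITUDE_SUM_TOL:
            raise ValueError(f"mixture weights must sum to 1 (got {sum(self.weights)!r})")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    def to_dict(self) -> dict:
        return {
            "species": [s.to_dict() for s in self.species],
            "weights": list(self.weights),
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureSpec":
        return cls(
            species=tuple(SpeciesSpec.from_dict(s) for s in d["species"]),
            weights=tuple(d["weights"]),
            noise_sigma=d.get("noise_sigma", 0.0),
            seed=d.get("seed", 0),
        )

    @classmethod
    def from_json(cls, path) -> "MixtureSpec":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# forward models

def gen_absorption(bands, axis: SpectralAxis) -> Spectrum:
    """Steady-state absorption spectrum: a sum of Gaussian bands."""
    bands = list(bands)
    if not bands:
        raise ValueError("at least one band is required")
    lam = axis.wavelengths
    values = np.zeros_like(lam)
    for band in bands:
        values += band.profile(lam)
    return Spectrum(axis, values)


def _channel_profile(bands, shift: ShiftModel | None, lam: np.ndarray, t: np.ndarray):
    """Sum of band profiles with an optional common center trajectory.

    ``lam`` has shape (1, n_lambda) and ``t`` (n_t, 1); the result is the
    full (n_t, n_lambda) surface.
    """
    out = np.zeros((t.shape[0], lam.shape[1]))
    offset = shift.offset(t) if shift is not None else 0.0
    for band in bands:
        out += band.profile(lam, center=band.center + offset)
    return out


def gen_species_map(spec: SpeciesSpec, saxis: SpectralAxis, taxis: DelayAxis) -> TAMap:
    """Noiseless single-species TA map from the model in the module docstring."""
    if len(saxis) < _MIN_AXIS_LEN or len(taxis) < _MIN_AXIS_LEN:
        raise ValueError(f"generator axes need at least {_MIN_AXIS_LEN} samples")
    total = sum(k.amplitude for k in spec.kinetics)
    if abs(total - 1.0) > _AMPLITUDE_SUM_TOL:  # defensive: specs are validated on build
        raise ValueError("kinetic amplitudes must sum to 1")

    lam = saxis.wavelengths[None, :]
    t = taxis.delays[:, None]
    P = spec.survival(t)

    esa = _channel_profile(spec.esa_bands, spec.esa_shift, lam, t)
    se = _channel_profile(spec.se_bands, spec.se_shift, lam, t)
    gsb = spec.gsb_band.profile(lam)

    osc = np.zeros_like(esa)
    for comp in spec.oscillations:
        osc += comp.modulation(lam, t)

    prod = spec.product_band.profile(lam) if spec.product_band is not None else 0.0

    dod = (
        P * (esa - se) * (1.0 + osc)
        - P * gsb
        + spec.phi_iso * (1.0 - P) * (prod - gsb)
    )
    return TAMap(saxis, taxis, dod)


def gen_mixture(spec: MixtureSpec, saxis: SpectralAxis, taxis: DelayAxis) -> TAMap:
    """Weighted sum of species maps plus iid Gaussian noise (reproducible
    from ``spec.seed``)."""
    dod = np.zeros((len(taxis), len(saxis)))
    for w, sp in zip(spec.weights, spec.species):
        dod += w * gen_species_map(sp, saxis, taxis).dod
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        dod = dod + rng.normal(0.0, spec.noise_sigma, size=dod.shape)
    return TAMap(saxis, taxis, dod)


def gen_double_pump(
    at_spec: SpeciesSpec,
    k_spec: SpeciesSpec,
    f_at: float,
    saxis: SpectralAxis,
    taxis: DelayAxis,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> TAMap:
    """Two-pump experiment: an actinic pulse leaves a relaxed mixture of the
    resting state (fraction ``f_at``) and the photocycle intermediate K
    (fraction 1 - f_at), probed long (~60 ps) after the actinic excitation so
    both are in their ground states when the second pump arrives."""
    if not 0.0 <= f_at <= 1.0:
        raise ValueError(f"f_at must lie in [0, 1], got {f_at}")
    mixture = MixtureSpec(
        species=(at_spec, k_spec),
        weights=(f_at, 1.0 - f_at),
        noise_sigma=noise_sigma,
        seed=seed,
    )
    return gen_mixture(mixture, saxis, taxis)


# ---------------------------------------------------------------------------
# dipole-strength helpers (integrals are energy-domain quantities)

def band_wavenumber_integral(band: Band, n_points: int = 20001, n_sigma: float = 10.0) -> float:
    """Integrated band strength in OD·cm^-1: the band profile integrated over
    wavenumber ν̃ = 1e7/λ, evaluated on a dense wavelength grid."""
    lo = max(band.center - n_sigma * band.width, 1.0)
    hi = band.center + n_sigma * band.width
    lam = np.linspace(lo, hi, n_points)
    values = band.profile(lam)
    wn = NM_TO_WAVENUMBER / lam  # descending
    return float(np.trapezoid(values[::-1], wn[::-1]))


def band_for_dipole_ratio(
    reference: Band, center: float, width: float, ratio: float
) -> Band:
    """A Gaussian band at (center, width) whose wavenumber-integrated
    strength is ``ratio`` times that of ``reference``.

    Used to encode the ~15% larger absorption dipole strength of the
    all-trans photoproduct relative to the 13-cis reactant."""
    if ratio <= 0:
        raise ValueError("dipole ratio must be positive")
    unit = Band(center, width, 1.0)
    amp = ratio * band_wavenumber_integral(reference) / band_wavenumber_integral(unit)
    return Band(center, width, amp)


# ---------------------------------------------------------------------------
# default species fixtures (the study conditions)

def default_at_spec(
    rel_osc_amplitude: float = 0.08,
    osc_wavenumber: float = 180.0,
) -> SpeciesSpec:
    """All-trans (light-adapted) resting state.

    Ground-state band at 570 nm; ESA near 480 nm; SE in the NIR; ~0.5 ps
    single-exponential excited-state decay with ~equal branching to the K
    photoproduct (590 nm); a low-frequency coherent mode modulating the
    signal near 520 nm.
    """
    gsb = Band(570.0, 45.0, 0.010)
    return SpeciesSpec(
        gsb_band=gsb,
        esa_bands=(Band(480.0, 30.0, 0.008),),
        se_bands=(Band(900.0, 120.0, 0.007),),
        product_band=Band(590.0, 48.0, 0.0094),
        kinetics=(KineticComponent(1.0, 0.5),),
        phi_iso=0.5,
        oscillations=(
            OscComponent(
                wavenumber=osc_wavenumber,
                damping_tau=0.6,
                phase=0.0,
                rel_amplitude=rel_osc_amplitude,
                window_center=520.0,
                window_width=30.0,
            ),
        )
        if rel_osc_amplitude > 0
        else (),
    )


def default_c13_spec(phi_iso: float = 0.55, dipole_ratio: float = 1.15) -> SpeciesSpec:
    """13-cis,15-syn dark-adapted component.

    Ground-state band at 543 nm; ultrafast (tau = 0.15 ps) decay so its
    excited-state signal is numerically extinct by ~0.6 ps; blue-shifting
    ESA and red-shifting SE (ballistic isomerization); photoproduct is the
    all-trans band at 570 nm carrying ``dipole_ratio`` times the reactant's
    wavenumber-integrated strength.
    """
    gsb = Band(543.0, 40.0, 0.010)
    return SpeciesSpec(
        gsb_band=gsb,
        esa_bands=(Band(470.0, 30.0, 0.008),),
        se_bands=(Band(880.0, 110.0, 0.007),),
        product_band=band_for_dipole_ratio(gsb, 570.0, 45.0, dipole_ratio),
        esa_shift=ShiftModel(470.0, 445.0, 0.12),
        se_shift=ShiftModel(880.0, 960.0, 0.12),
        kinetics=(KineticComponent(1.0, 0.15),),
        phi_iso=phi_iso,
    )


def default_k_spec(reform_at: bool = True) -> SpeciesSpec:
    """K photocycle intermediate (13-cis,15-anti, absorbing at 590 nm).

    Biexponential excited-state decay with equal-amplitude 1.7 ps and 11 ps
    components; photoexcitation either isomerizes K back to the all-trans
    ground state (``reform_at``) or reforms K.  No coherent oscillation:
    the coherence marker is exclusively a resting-state signature in the
    two-pump decomposition.
    """
    gsb = Band(590.0, 50.0, 0.010)
    return SpeciesSpec(
        gsb_band=gsb,
        esa_bands=(Band(480.0, 32.0, 0.008),),
        se_bands=(Band(860.0, 110.0, 0.007),),
        product_band=Band(570.0, 45.0, 0.0096) if reform_at else None,
        kinetics=(KineticComponent(0.5, 1.7), KineticComponent(0.5, 11.0)),
        phi_iso=0.5 if reform_at else 0.0,
    )
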