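# Methods

## Signal model

All analysis operates on ΔOD(λ, t) surfaces (wavelength in nm, pump–probe
delay in ps, signal in OD). The synthetic generator builds a species'
surface from four Gaussian band families — excited-state absorption (ESA,
positive), stimulated emission (SE, negative), ground-state bleach (GSB,
negative at the reactant band) and a photoproduct band (positive) — tied
together by the excited-state survival probability
P(t) = Σᵢ Aᵢ e^(−t/τᵢ) (Σ Aᵢ = 1) and an isomerization quantum yield φ:

    ΔOD(λ,t) = P(t)·[σ_ESA(λ,t) − σ_SE(λ,t)]·(1 + osc(λ,t))
               − P(t)·σ_GS(λ)
               + φ·(1 − P(t))·[σ_prod(λ) − σ_GS(λ)]

At t → ∞ this converges to φ·(σ_prod − σ_GS), the long-delay difference
spectrum; with φ = 0 the ground state recovers completely. Two optional
features model the fine structure the decomposition methods rely on:

* **Ballistic band shifting.** ESA/SE centers can follow
  center(t) = end + (start − end)·e^(−t/τ_shift), the signature of
  continuous wave-packet motion toward the crossing seam.
* **Coherent oscillations.** A multiplicative modulation of the
  excited-state term, osc = Σⱼ aⱼ·g(λ)·e^(−t/τ_d)·cos(2πc·ν̃ⱼ·t + φⱼ),
  spectrally windowed by a unit-peak Gaussian g(λ) (default center
  520 nm), with ν̃ in cm⁻¹ and c the speed of light in cm/ps.

A mixture is a convex combination of species surfaces plus iid Gaussian
pixel noise drawn from one seeded generator. Mixture weights are the
excited-population fractions; pumping at the isosbestic point of the
co-resident isomers makes these equal to the ground-state fractions, which
is asserted as an assumption, not computed.

### What the generator emulates — and what it does not

Emulated: band superposition with independent species contributions,
multi-exponential decay on the conventional linear+log delay axis, the
fast (τ = 0.15 ps) 13-cis channel with blue-/red-shifting ESA/SE, the
equal-amplitude 1.7/11 ps biexponential K channel, spectrally localized
damped coherence, the two-pump experiment (a relaxed AT+K ground-state
mixture re-excited 60 ps after actinic excitation), isosbestic pumping,
additive white noise.

Not emulated: instrument response and coherent artifacts (data before
80 fs are simply excluded from analysis windows, mirroring practice),
probe chirp/group-velocity dispersion, pump scatter, correlated baseline
noise, S₂ contributions, vibrational cooling band narrowing, and any
explicit conical-intersection dynamics. Passing tests therefore
demonstrate estimator correctness under the stated statistical model, not
robustness to instrument systematics.

## Default species (the study conditions)

| species | GSB | ESA | SE | kinetics | φ | extras |
|---|---|---|---|---|---|---|
| AT (light-adapted) | 570/45 nm, 0.010 OD | 480/30 nm, 0.008 | 900/120 nm, 0.007 | 1 × 0.5 ps | 0.5 | 180 cm⁻¹ mode, damping 0.6 ps, 8% depth, window 520/30 nm |
| 13C (dark-adapted minor) | 543/40 nm, 0.010 | 470/30 nm, 0.008, shifting → 445 nm (τ 0.12 ps) | 880/110 nm, 0.007, shifting → 960 nm | 1 × 0.15 ps | 0.55 | product = AT band at 570/45 nm with 1.15× the reactant's wavenumber-integrated strength |
| K (photocycle intermediate) | 590/50 nm, 0.010 | 480/32 nm, 0.008 | 860/110 nm, 0.007 | 0.5 × 1.7 ps + 0.5 × 11 ps | 0.5 | product = AT band (K\* returns to AT or reforms K); no coherence |

Band positions follow the species' known absorption maxima and the
ESA/SE probe windows used in practice; amplitudes (~10 mOD bleach) are
typical of purple-membrane TA at moderate excitation. The 13C shift
magnitudes are free parameters (no quantitative literature values) chosen
once to produce a clearly resolvable ballistic signature. Signal-axis
sizes used throughout tests and the acceptance script: 100–240 probe
pixels, 70–300 delays — small enough that the whole suite runs in
seconds while leaving every estimator's statistics intact.

Delay axes come in two flavours, matching acquisition practice: the
standard linear (20 fs steps to 0.5 ps) + logarithmic (to 100 ps) axis
for kinetic work, and a uniform 10 fs grid to 3 ps for coherence-resolved
analysis — a 180 cm⁻¹ mode (186 fs period) is not resolvable on the
log-spaced tail, so oscillation studies use the dense grid.

## Scale-factor estimators

All four markers reduce to the same closed-form scalar least squares,
c = ⟨m, p⟩/⟨p, p⟩ for marker signals m (mixture) and p (pure), and report
a residual norm plus a standard error.

**ΔΔOD (dynamic difference) marker.** ΔΔOD = ΔOD(t₂) − ΔOD(t₁) cancels
every static contribution, so after the fast species' excited state is
gone only the pure species' dynamics remain. Defaults: t_min = 0.6 ps;
spectral mask restricted to excited-state-dominated windows, 440–500 nm
(ESA) plus 850–1400 nm (SE), configurable. Delay pairs default to
*late-anchored* differences (every t ≥ t_min against the final delay):
anchored differences measure the remaining excited-state amplitude at t,
whereas consecutive-pair differences measure its derivative, which
amplifies a fast contaminating species by τ_slow/τ_fast. With the 0.15 ps
13C channel this choice reduces the contamination bias from ~0.03 to
~0.01 at the prescribed t_min; both pairings (and arbitrary staged pairs)
remain available through the `pairs` argument. Uncertainty is a
delete-one-pair jackknife — the assumption-lightest option given the
strongly unequal information content of the pairs.

**Coherence marker.** Band-averaged traces at the oscillation window
(default 520 ± 10 nm) are stripped of population kinetics by a
multi-exponential fit (default biexponential, the standard practice);
the factor scales the pure residual onto the mixture residual over
t ∈ [0.08, 3] ps. Two safeguards matter:

* fitted lifetimes are floored at `min_kinetic_tau` (default 0.2 ps,
  about one period of the slowest mode of interest) — a faster component
  is mathematically indistinguishable from a coherence lobe and would
  absorb oscillation amplitude asymmetrically between the two traces;
* the pure residual must show an isolated vibrational peak (≥ 60 cm⁻¹,
  10× the median FFT power) *and* an RMS above 3× the second-difference
  noise floor, otherwise the estimator refuses ("no coherence marker")
  rather than scaling noise onto noise.

The method assumes the coherence is exclusively a pure-species signature;
if the second species carries correlated modulation the factor is biased
upward by its relative amplitude (quantified in the test suite).

**NIR SE marker.** Raw-amplitude least squares restricted to the
900–1400 nm window and t ∈ [0.6, 5] ps, where stimulated emission is an
exclusive S₁-population measure. Using an early window (before the fast
species' SE has decayed) biases the factor upward; the bias direction is
asserted in tests as documentation.

**Late-spectrum match.** Proportionality factor between time-averaged
spectra for t ≥ t_min; used as a consistency check (for the two-pump
experiment the factor exceeds 1, consistent with K\* returning to K or
AT).

## Kinetics

`fit_multiexp` minimizes ‖y − offset − Σ Aᵢe^(−t/τᵢ)‖² by variable
projection: amplitudes and offset are solved linearly at every lifetime
iterate, and the nonlinear search runs over log-lifetimes only
(scipy `least_squares`, TRF, tolerances 1e-14). Because linear+log axes
create local minima, 8 log-spaced multistart grids span 0.05–200 ps and
the best converged start wins; lifetimes are clipped to [0.01, 1000] ps
and a solution pinned at a bound warns. Reported lifetimes are sorted
ascending (the canonical form), standard errors come from the
Gauss–Newton covariance of the full nonlinear model, and for
biexponential fits the amplitude ratio A_fast/A_slow is reported with a
propagated error so "equal amplitudes" is a checkable statement.

Oscillatory residuals are trace − fit restricted to t ≥ 80 fs (the
coherent-artifact window). Spectral analysis resamples the residual onto
a uniform grid at the minimum native spacing (linear interpolation — a
small known low-pass bias on log-spaced tails), then either an FFT power
spectrum on a ν̃ = f/c axis (cm⁻¹) or damped-cosine least squares seeded
from the FFT peaks; requesting more components than resolvable peaks
degrades gracefully with a warning. Anisotropy follows
r = (ΔOD∥ − ΔOD⊥)/(ΔOD∥ + 2ΔOD⊥) with denominator-masked points reported
through an explicit validity mask instead of NaN propagation.

## Quantum yield

Band integrals are evaluated in wavenumber (dipole strengths are
energy-domain quantities): trapezoidal integration of the spectrum
against ν̃ = 10⁷/λ with interpolated window edges. After complete
excited-state decay each photoexcited molecule contributes
φ·(ε_prod − ε_reac) to the difference spectrum, whose integral over the
ground-state region is φ·D_reac·(r − 1) with r = D_prod/D_reac (the
product/reactant dipole-strength ratio, ~1.15 for all-*trans* vs 13-*cis*
retinal pigments); the early bleach integrates to D_reac. Hence

    φ = I_long / (|I_bleach| · (r − 1)).

This reconstruction is the minimal band-integral model consistent with
the approach; results carry `formula="reconstructed"` and its correctness
standard is round-trip recovery on synthetic ground truth (φ = 0.55
recovered to better than 0.01 with the default 430–700 nm window).
Isolating a clean early bleach (free of ESA/SE overlap) is the caller's
responsibility — from a decomposed pure-species map at an early delay or,
for synthetic studies, from the generator's ground-truth GSB band. Yields
outside [0, 1] are returned unclipped with an `out_of_range` flag;
sensitivity to a misassumed r is roughly dφ/dr ≈ −φ/(r − 1), so ±0.05 on
r moves φ by ∓30% — r is the dominant systematic.

## Numerical and design choices

* Bands are Gaussian in wavelength (not wavenumber) for construction
  simplicity; integrals that represent dipole strengths are always taken
  in wavenumber, and the helper `band_for_dipole_ratio` calibrates a
  band's wavenumber-integrated strength exactly.
* Peak positions (λmax) use 3-point parabolic interpolation through the
  grid maximum; exact ties break toward the longer wavelength; edge peaks
  and non-concave brackets return the grid point itself. Negative dips in
  decomposed spectra are reported, never clipped (clipping would bias
  λmax), with a warning.
* File I/O is plain TSV with `repr`-serialized floats (bit-exact round
  trips), `# key=value` provenance comments (tool version, seed,
  command), hard failures on non-monotone axes, ragged rows, NaN cells
  and decimal commas. Units are fixed at nm/ps/OD; mOD and fs conversion
  is explicit, never guessed.
* Containers require ≥ 2 axis samples; the generator factories require
  ≥ 8 (a generated map with fewer points cannot carry band structure).
  Hand-written miniature files remain loadable for testing.
* All randomness flows through `numpy.random.default_rng` from a single
  integer seed per generated object; identical specs produce bitwise
  identical maps.

## Known limitations

* The ΔΔOD and SE factors retain a small positive bias (~0.01 at the
  default windows) from the exponential tail of the fast species; a
  truly ballistic (sharper-than-exponential) decay would remove it. The
  uncertainty reported by the jackknife does not include this systematic.
* The coherence marker assumes mode exclusivity; correlated coherence in
  the second species biases it upward by the relative modulation depth.
* No instrument-response deconvolution anywhere: lifetimes much below
  ~50 fs are outside the model space, consistent with discarding t < 80 fs.
* FFT frequencies inherit the resampling interpolation bias on strongly
  nonuniform axes; damped-cosine fits on the native grid do not.
* `estimate_qy` corrects the early bleach for excited-state overlap only
  through window choice; a contaminated bleach reference propagates
  directly into φ.
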