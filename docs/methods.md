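# Methods

This note records the models implemented in `quenchbind`, their
assumptions, the defaults and why they were chosen, and the limits of what
the synthetic-data tests can demonstrate.

## Quenching and binding models

**Stern–Volmer.** Quenching of the protein donor's steady-state emission
obeys F₀/F = 1 + K_sv[Q] for a single quenching process.  The model is fit
by ordinary least squares of F₀/F on [Q]; the [Q] = 0 point contributes the
exact datum (0, 1).  F₀ is the *measured* zero-quencher intensity, not a
fitted parameter — this matches the ratio formulation of the analysis and
avoids absorbing baseline error into the slope.  The intercept is free by
default; `constrain_intercept=True` fixes it at 1 (closed-form regression
through (0, 1)), since instrument conventions differ and neither choice is
universal.  The bimolecular rate constant is k_q = K_sv/τ₀ with
τ₀ = 1×10⁻⁸ s, the standard assumption for tryptophan emission when no
lifetime instrument is available.

**Mechanism classification.** Static quenching (ground-state complex) is
called when K_sv *strictly decreases* over the supplied temperatures and
every k_q exceeds the diffusion-collision ceiling of 2×10¹⁰ M⁻¹s⁻¹;
dynamic when K_sv strictly increases and k_q stays at or below it.  Any
other pattern — including the combined static+dynamic regime, which shows
as Stern–Volmer curvature — is reported as *indeterminate* with a
diagnostic note rather than resolved; fitting two-constant combined models
is out of scope.  With the typical three temperatures the trend test is
strict monotonicity, not a regression.

**Hill isotherm.** Binding is modelled as
(F₀−F)/F₀ = K_A[Q]ⁿ/(1+K_A[Q]ⁿ).  The fractional-quenching response is
bounded in [0, 1), which conditions the fit far better than fitting F
directly; weights are uniform.  The nonlinear fit works in (log₁₀K_A, n),
started from the linearized regression of log₁₀((F₀−F)/F) on log₁₀[Q] and
repeated from 5 starting points log-spaced ±1 decade around that estimate
(lowest residual sum wins).  Points with F ≥ F₀ are excluded from the
linearized fit with a warning (their log is undefined) but retained in the
nonlinear residuals.  Reported uncertainties are fit standard errors from
the covariance; replicate-based errors are the caller's responsibility.

**K_A–n identifiability.** At the titration design used here
([Q] ≲ 2×10⁻⁴ M), K_A carries units of M⁻ⁿ, so the free-n fit exhibits a
near-perfect correlation between log K_A and n:
δ(ln K_A) ≈ |ln Q̄|·δn ≈ 9·δn.  At 1 % multiplicative noise the free fit
recovers n to ±0.02 but K_A only to ~15 % (median; `scripts/acceptance.py`
reports both recovery errors).  A binding constant
quoted to a few percent therefore presumes the noncooperative convention
n = 1 — which is how such studies report it ("n = 1 ± 0") — and the
package exposes `fix_n=1` for exactly that.  The recovery benchmarks check
n on the free fit and K_A under the fixed-n convention.

**Site-marker displacement.** The ratio K_A(marker)/K_A(free) is
interpreted as direct competition when it falls below 0.5 with n unchanged
(|Δn| ≤ 0.2), as no direct competition at the probed site when ≥ 1 with n
unchanged, and as ambiguous otherwise.  All three thresholds are
parameters.

## Thermodynamics

ln K_A is regressed on 1/T (R = 8.314 J·mol⁻¹·K⁻¹): ΔH° = −R·slope,
ΔS° = R·intercept, ΔG°(T) = ΔH° − TΔS°.  Units are deliberately mixed to
match reporting convention — ΔH°, ΔG° in kJ·mol⁻¹, ΔS° in J·mol⁻¹·K⁻¹ —
and all conversions are centralized.  With two temperatures the line is
exact and standard errors are undefined (reported as NaN); with three, r²
is reported but not used for gating.  The linear model assumes
temperature-independent ΔH° over the narrow 20 K span; curved Van't Hoff
variants are out of scope.

Force classification follows the Ross–Subramanian sign quadrants:
(−, −) → hydrogen bonding/van der Waals, (−, +) → electrostatic,
(+, +) → hydrophobic.  The fourth quadrant (+, −) is flagged `invalid`
(implausible for spontaneous association).  |ΔH°| < 1 kJ·mol⁻¹ or
|ΔS°| < 1 J·mol⁻¹·K⁻¹ sets a weak-evidence flag, since a sign read off a
near-zero estimate is not evidence of a force type.  Docking energies in
kcal·mol⁻¹ convert with the thermochemical factor 4.184.

## Inner-filter correction

The default correction is the standard F_cor = F_obs·10^((A_ex+A_em)/2).
A variant that circulates in the albumin-binding literature,
F_cor = F_obs·e^((A_ex−A_em)/2), is retained behind
`mode="literature_alt"`: for matched absorbances its exponent is zero, so
it cannot remove attenuation, and it is never the default.  The simulator
can apply the exact inverse distortion (absorbances proportional to [Q],
1 cm path), which makes distort-then-correct an identity — this validates
the plumbing, not the photometric accuracy of the correction on real
cuvette geometries.

## FRET

J = ∫F(λ)ε(λ)λ⁴dλ/∫F(λ)dλ is evaluated by the composite trapezoid rule
after resampling both spectra to a common 1 nm grid over the intersection
of their ranges (≥ 5 nm required).  With λ in nm and ε in M⁻¹cm⁻¹, the
Förster constant 0.211 yields R₀ in Å; the return value is converted to
nm.  κ² presets: 0.667 (dynamic orientational averaging) and 0.475
(static); arbitrary κ² ∈ [0, 4] is accepted.  The efficiency/distance
relation implemented is E = R₀⁶/(R₀⁶+r⁶) — the form with a minus sign in
the denominator that appears in parts of the literature yields E outside
[0, 1] and is inconsistent with any published (R₀, r, E) triple.
Distances are flagged valid only inside 2–8 nm *and* 0.5R₀–1.5R₀ (bounds
inclusive).  Note on the medium refractive index: 1.336 (aqueous buffer)
is the conventional value, but published radii for this class of system
are often only reproducible with n ≈ 1.36; the parameter is therefore
exposed rather than hard-coded (R₀ ∝ n⁻²ᐟ³, so the two choices differ by
about 1 % in R₀).

## Conformational diagnostics

*Synchronous scans* (Δλ = 15 nm → Tyr, 60 nm → Trp): λ_max is the largest
prominence-filtered peak, refined by 3-point parabolic interpolation; a
shift beyond ±1 nm (the typical instrument step) is read as increased
polarity (red) or hydrophobicity (blue).  *EEM*: peak A is the intensity
maximum on the first-order Rayleigh ridge |λ_em−λ_ex| ≤ 5 nm; off-ridge
strict local maxima are labelled B (ex≈280/em≈340, Trp+Tyr) or C
(ex≈236/em≈335, polypeptide) when within 15 nm of those canonical
coordinates.  Coordinates and radius are configuration, not constants of
nature.  *CD*: helix content uses the single-wavelength estimator
%α = 100·(−MRE(208)−4000)/29000, with raw ellipticity converted via
MRE = θ·MRW/(10·l·c) (MRW = 66430/583 ≈ 113.9 g·mol⁻¹ per residue for
bovine serum albumin).  This estimator is affine in MRE(208) and anchored
at coil (−4000) and helix (−33000) limits; it is *not* a deconvolution,
and published helix percentages from CONTIN-class methods will generally
not be reproduced exactly from the same spectrum.

## Numerical choices

- Savitzky–Golay second derivatives (quadratic polynomial) require a
  uniform grid (resample first); edge samples are padded with the nearest
  interior estimate.  The smoothing window is exposed because instrument
  practice varies; default 7 points.
- Peak picking: prominence threshold as a fraction of the spectrum
  maximum; plateau ties break toward the lower wavelength; parabolic
  refinement is clipped to ±half a grid step.
- Degenerate inputs raise rather than guess: E ∈ {0, 1} in the distance
  inversion, zero donor integral in J, non-overlapping spectra, duplicate
  wavelengths or temperatures, fewer than 3 (Stern–Volmer) or 4 (Hill)
  informative points.
- r² is clipped to [0, 1] for the constrained-intercept and nonlinear
  fits, where the raw 1−SS_res/SS_tot can go negative on pathological
  data.

## Synthetic data: what it does and does not show

The generator emulates the study conditions of a serum-albumin titration:
4 µM-scale donor with a single emission band near 340 nm (excitation
280 nm), a quinoline-like acceptor absorbing near 254 nm, the 11-point
0–170 µM quencher design, temperatures 290/300/310 K, binding constants
placed exactly on a Van't Hoff line through (ΔH°, ΔS°), and multiplicative
Gaussian noise (constant relative error, the simplest model consistent
with roughly uniform scatter in such plots; negative draws are resampled).
The dynamic-mechanism branch uses an Arrhenius-activated K_sv(T)
(default activation energy 20 kJ·mol⁻¹ — chosen only to exercise the
classifier, as no experimental value exists for a hypothetical collisional
channel).  Gaussian bands are truncated at 5σ so that nominally disjoint
spectra have exactly zero overlap.

Passing the generative round trips shows the estimators invert the stated
models correctly and that the pipeline is self-consistent; it does not
validate the models against real fluorometer artifacts the generator omits:
photobleaching, scattering baselines, detector saturation, wavelength
calibration error, or correlated (non-multiplicative) noise.

## Pipeline defaults and problem sizes

The full pipeline (`run_full_analysis` / `quenchbind run`) executes
quenching → binding → thermodynamics → FRET → conformation; the
quenching/binding core aborts on failure, optional stages degrade to
warnings recorded in the report.  The FRET efficiency point defaults to
the 5 µM titration point at the highest temperature (physiological), as
transfer-efficiency estimates should use small quencher excess.  The
stochastic recovery benchmark uses 200 replicates of the 11-point design
at 1 % noise at 310 K — large enough for a stable median, small enough to
run in seconds.  All randomness flows from a single integer seed;
identical configs and seeds produce byte-identical JSON reports.
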