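# Methods

## The physical model

A rigid sphere of radius *R* indented a depth *δ* into a fluid-saturated
linear isotropic elastic half-space pressurizes the interstitial fluid;
the pressure relaxes by diffusion through the pore network with an
effective diffusivity *D*.  The poroelastic length scale is the contact
radius *a* = √(*Rδ*), and the relaxation time scale is *a*²/*D*.  A ramp
of duration *t_R* (rise time) is therefore fast or slow only relative to
that time scale, measured by the dimensionless rise time

    τ_R = D·t_R / (R·δ_M).

Two Hertzian limits bracket the maximum ramp force *F_M*:

- *instantaneous* (undrained) loading, τ_R → 0: the fluid cannot
  redistribute, the composite is incompressible (ν = 0.5) and
  F = (4/3)√R δ_M^{3/2} E / 0.75;
- *drained* loading, τ_R → ∞: the fluid is fully equilibrated and the
  response uses the material's drained Poisson ratio ν, denominator
  (1 − ν²).

Mapping *F_M* affinely between those limits,

    F*_M(τ_R) = [F_M/((4/3)√R δ_M^{3/2} E) − 1/(1−ν²)] / [1/0.75 − 1/(1−ν²)],

collapses maximum-force versus rise-time data of any geometry onto a
single dimensionless master curve, represented empirically by the
stretched exponential

    F*(τ_R) = A·exp(−b·τ_R^p),   A = 12.5, b = 2.63, p = 0.12.

Matching the two expressions over a handful of ramp tests at different
approach velocities — no hold-phase data, no finite-element model —
identifies (E, ν, D) by root-mean-square error minimization.  The drained
elastic modulus, Poisson ratio and diffusivity further give the hydraulic
permeability through K = D(1−2ν)(1+ν)/(E(1−ν)), singular at ν = 0.5
(raised as an error, never returned as 0).

### The clamp policy

The stretched exponential exceeds 1 for τ_R below its unit-crossing point
τ₀ = (ln A / b)^{1/p} ≈ 0.7138, although F*_M ≤ 1 by construction.  The
coefficients were calibrated against simulation data; their behavior
below τ₀ is extrapolation.  Forward predictions therefore clamp the
empirical value at 1 (so predicted forces stay inside the physical Hertz
bracket), and fits flag — but never drop — observations whose fitted τ_R
falls below τ₀: in that region the maximum force has saturated at the
undrained limit and carries no rate information, only a constraint on E.
`clamp=False` reproduces the raw formula.

## The inverse fit

`PoroelasticMasterCurveFit` minimizes the unweighted RMS of
F*_M(obs; E, ν) − F*(τ_R(D)) over the observation set (per-point weights
are available as a config option).  Numerics:

- **E is profiled out in closed form.**  F*_M is affine in s = 1/E, so
  the optimal E at any (ν, D) is a one-line weighted least-squares
  solution.  The search space is then two-dimensional.
- **Dense vectorized grid + zoom.**  251 ν points on [0, 0.49] × 121
  log-D points spanning ±3 decades around the scaling guess
  D₀ = median(Rδ_M/t_R) (the value placing a mid-range observation at
  τ_R = 1), followed by an iterated per-ν-row bracketing zoom on D.  The
  density matters: with exact (noise-free) data the global RMS basin near
  high ν can be needle-thin in both ν and D, and coarse grids converge to
  broad secondary basins instead.
- **Multi-start Nelder-Mead refinement** from the three best
  well-separated ν rows, in (logit ν, log D) with tolerances 1e-10, each
  start restarted once (simplex refinement can stall early).
- **Uncertainties** are nonparametric bootstrap standard deviations over
  observations (200 resamples by default, seeded, refined from the point
  estimate); resamples that lose all rise-time diversity are redrawn.
- Fewer than 3 observations, or a single distinct rise time, raises an
  underdetermined-fit error (D cannot be identified from one τ_R).

### Identifiability

ν enters the objective only through 1/(1−ν²) and the normalization
denominator 1/0.75 − 1/(1−ν²).  That denominator shrinks from 1/3 at
ν = 0 to 0.08 at ν = 0.45, with two consequences measured on synthetic
suites: (i) force noise is amplified into F* space by its inverse, so at
2% multiplicative force noise on the 24-test micro-indentation protocol
the unweighted objective prefers small ν (ν̂ collapses to the 0 bound for
most noise draws even when the true ν is 0.12) and D̂ scatter grows
steeply for true ν ≳ 0.4; and (ii) noiseless identification is exact to
optimizer tolerance across E ∈ [10, 70] kPa, ν ∈ [0.1, 0.45],
D ∈ [1e−10, 1e−8] m²/s.  Poisson-ratio estimates from this objective
should be read with that in mind; E and D are far more robust.  This is a
property of the estimation problem, not of the optimizer — the same
suites identify all three parameters exactly without noise.

## Normalization and collapse

Three curve normalizations are provided: the relaxation fraction
[F − F_∞]/[F_M − F_∞] (dimensionless, 1 → 0 over the hold), the
Hertz-scaled force F/(R^{1/2} δ_M^{3/2}) (units N·m⁻², removes geometry),
and the scaled time t/(Rδ_M) (units s·m⁻²; fully dimensionless only once
D is folded in).  F_∞ is estimated as the mean over the final 5% of the
hold with a relative tail-slope gate of 0.01 (an unconverged tail is
flagged, not rejected); F_M is the force at the end of the ramp rather
than the global maximum, for robustness to inertial overshoot spikes
(`fm_mode` configurable).  The collapse metric interpolates all curves
piecewise-linearly in log-time onto a shared 200-point log grid and
reports the worst vertical spread — 0 for perfect collapse; the test
suites use < 0.05 as "collapsed" and > 0.1 as "separated" (conventions,
not physical constants).

Dimensional analysis of the surrogate shows that, for one material,
normalized curves coincide exactly when t_R/(Rδ_M) matches — equivalently
when the effective velocity V_eff = √(Rδ_M)/t_R *and* the contact scale
Rδ_M match, which is how matched-collapse pairs are constructed here
(e.g. R = 5 mm, δ_M = 1 mm against R = 10 mm, δ_M = 0.5 mm at equal t_R).
Equal V_eff with different Rδ_M leaves a residual mismatch of order the
√(Rδ_M) ratio in τ_R.

## The synthetic-experiment generator

Two deliberately independent forward models replace instruments and
finite-element simulation.

**Ramp-suite generator** (`simulate_ramp_suite`): end-of-ramp records
straight from the master-curve model.  Displacement clamp evaluates the
forward force at each (δ_M, t_R); force clamp solves the depth implicitly
(Brent bracketing on [1 nm, R], relative tolerance 1e-10) with
t_R = δ_M/V resolved inside the root find.  Exactly self-consistent with
the inverse fit, hence the tool for recovery studies.

**Hereditary-integral surrogate** (`simulate_relaxation_curve`): full
force-time curves from

    F(t) = C_d·h(t) + (C_i − C_d)·∫₀ᵗ g(D(t−u)/a(t)²)·h'(u) du,

with h = δ^{3/2}, linear ramp δ(t) = δ_M·min(t, t_R)/t_R,
C_d = (4/3)√R·E/(1−ν²), C_i the same with 0.75, a(t) = √(Rδ(t)), and g a
step-response relaxation kernel.  Trapezoidal quadrature on a grid that
is linear over the ramp and log-spaced over the hold (400 + 1600 points
by default; the ramp endpoint is always a node); default hold duration 20
contact-diffusion times, enough to approach the drained limit to ≪ 1%.
The construction guarantees F(0) = 0, F(t_R) → undrained Hertz force as
t_R → 0, and F(∞) → drained Hertz force, and reproduces the
effective-velocity collapse.

Freezing the kernel argument at the *current* contact radius is an
approximation: it ignores re-pressurization from the advancing contact
edge during the ramp.  Measured against the master-curve forward model at
matched (E, ν, D), the surrogate's end-of-ramp force agrees within 3% in
the near-step (τ_R ≲ 0.15) and near-drained (τ_R ≳ 100) regimes but sits
up to ~7% low mid-range, which in normalized-force space is a large,
systematic offset: fitting the master curve to surrogate-generated
observations recovers E and ν well but biases D high by a factor ~2.5
(agarose-like parameters).  Surrogate data therefore exercise the
*relative* comparison between fitting frameworks and the collapse
properties; they are not a calibration standard for the master curve, and
agreement between the two models is asserted only in the regimes where
they are consistent by construction.

**Noise model**: multiplicative Gaussian on force (typical σ = 1–2%,
matching a good load cell / AFM photodiode at these force scales) and
optional additive depth noise, applied after all deterministic solves and
fully determined by the protocol seed (byte-identical outputs per seed).
Real instruments additionally exhibit drift, contact-point uncertainty
and inertial overshoot, none of which the generator emulates — passing
recovery tests show correctness of the estimation machinery under the
stated noise model, not robustness to every instrumental artifact.

**Protocol presets** mirror the experimental campaigns the package
targets: a force-clamp AFM series (R = 25 µm; F_M = 500/1000/1600 nN ×
V = 320, 160, 80, 40, 20, 10, 5, 1 µm/s → 24 tests, kHz sampling) and
displacement-clamp macro series (R = 5–10 mm spheres; e.g. δ_M = 1/2/3 mm
× t_R = 1000/2000/3000 s for a slow-draining gel; 10 Hz sampling).

## The relaxation-only baseline

The classical alternative fits the normalized hold phase to a
step-response master function of τ = D·t/a², here the widely used
spherical-indentation kernel

    g(τ) = 0.491·exp(−0.908·√τ) + 0.509·exp(−1.679·τ)

(external literature; pluggable — any g with g(0) = 1, monotone to 0, is
accepted).  The fit is a log-grid global search over
D ∈ [1e−13, 1e−5] m²/s with bounded scalar refinement.  Because the
construction assumes an instantaneous ramp, its D̂ is biased low once
t_R is comparable to a²/D; on surrogate suites the bias grows
monotonically with τ_R (D̂/D ≈ 0.9 at τ_R ≈ 0.07 down to ≈ 0.4 at
τ_R ≈ 7), which is the behavior the comparison report
(`compare_frameworks`) is built to expose.

## Key parameters

| Parameter | Units | Default | Notes |
|---|---|---|---|
| A, b, p | – | 12.5, 2.63, 0.12 | master-curve coefficients |
| ν search bounds | – | [0, 0.49] | 0.5 singular; auxetic opt-in |
| grid (ν × log D) | – | 251 × 121 | D span ±3 decades around D₀ |
| bootstrap resamples | – | 200 | seeded |
| F_∞ tail window / slope gate | – | 5% / 0.01 | hold-phase tail mean |
| collapse grid | – | 200 log-spaced points | shared x-range |
| surrogate grid | – | 400 ramp + 1600 hold | trapezoid |
| validity warnings | – | δ/R > 0.6; a/h > 0.1 | Hertz / thin-sample |

Problem sizes in the test and acceptance suites (24-observation AFM
suites, 9–12 curve macro suites, 27-point recovery grids, 150–800-point
surrogate grids) were chosen so every study runs in seconds while keeping
quadrature and optimizer errors well below the asserted tolerances.

## Limitations

- Linear isotropic poroelasticity, frictionless impermeable spherical
  contact, half-space geometry.  Adhesion, conical/flat punches,
  finite-thickness corrections and hyperelasticity are out of scope;
  δ/R > 0.6 and a/h > 0.1 raise warnings only.
- The master-curve coefficients are taken as given, not re-derived; their
  sub-τ₀ behavior is an extrapolation handled by the clamp policy.
- The hereditary surrogate is a scaling-faithful stand-in, not a
  finite-element solution; see the cross-model discussion above.
- Intrinsic viscoelasticity is not modeled; on real materials whose
  viscous time scales overlap the poroelastic ones the recovered D
  conflates both mechanisms.
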