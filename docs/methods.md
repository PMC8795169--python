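# Methods

## Model overview

The package connects three layers of the microdosimetric quality-factor
workflow.

**Spectra.** A single-event lineal-energy spectrum is a discretized
density on a strictly positive, strictly increasing grid of *y* values
(keV/µm), tagged as frequency-weighted *f*(*y*) or dose-weighted
*d*(*y*) = *y f*(*y*)/∫*y f*(*y*)d*y*. All integrals use the trapezoid
rule on the stored grid; the integrator is grid-agnostic, so spectra
spanning several decades should be supplied on log-spaced grids. Every
constructor and transform renormalizes to unit integral (tolerance
1e-9). Because the grid excludes *y* = 0, the dose→frequency inverse
(*f* ∝ *d*/*y*) is always well defined and the round trip is the
identity to ~1e-12.

**Triangular surrogate.** For a mono-energetic beam crossing a
spherical site, the chord-length distribution makes the single-event
lineal energy approximately triangular. We realize this as the
frequency density *f*(*y*) = 2*y*/*y*²_max on (0, *y*_max] with
*y*_max = (3/2)·LET — the unique triangular form jointly consistent
with the sphere mean-chord identity ȳ_F = LET and the dose-mean
relation ȳ_D = (9/8)·LET. The generated grid is linear from
*y*_max/*n*_bins to *y*_max. At the default *n*_bins = 512 the
discretized dose mean matches (9/8)·LET to better than 1e-5 relative;
at the minimum allowed 16 bins the pointwise-trapezoid error is ≈0.2%,
and it decays as 1/*n*². Site diameter is carried as metadata only: the
surrogate is diameter-independent, which matches the observation that
diameter (2–16 µm) has only a moderate effect on real spectra. The
surrogate has no analogue of energy deposited by tracks that miss the
target; see Limitations.

**Dose–response.** Tumor yield at dose *D* of radiation type *i* is

    M_i(D) = B + T_i D + N_i (1 − exp(−s D)),

background *B* (tumors/mouse) plus a linear targeted-effect (TE) term
and a saturating non-targeted-effect (NTE) term. Per-mouse counts are
Poisson with mean *M*; this makes group totals sufficient and is the
standard choice for tumor multiplicity. *B* and *s* are shared across
all groups (the unirradiated controls are a single cohort; the NTE
saturation rate is common by assumption), the γ-ray group supplies the
reference *T*_γ, *N*_γ, and ion slopes obey *T*_i ≥ *T*_γ,
reparameterized as *T*_i = *T*_γ + δ_i with δ_i ≥ 0 so a box-bounded
quasi-Newton optimizer (L-BFGS-B with analytic gradients) applies
directly. The multistart uses one moment-based initial point plus 50
uniform-random restarts by default (seeded, deterministic). *s* is
bounded above at 500 Gy⁻¹; beyond that the NTE term is saturated at
every dose in the design and the parameter is unidentifiable anyway.

Confidence intervals: profile likelihood by default, inverting the
χ²(1) 95% cutoff (3.84) with an outward walk plus bisection; a bound
that runs into a constraint (e.g. δ_i = 0, the active *T*_i = *T*_γ
constraint) is reported at the constraint, which reproduces the
one-sided behavior seen when several ion slopes pin to the γ value. A
nonparametric case-resampling bootstrap (per mouse, within each
label×dose group) is the alternative. Effect-metric CIs use bootstrap
ratio percentiles when replicates exist, otherwise a delta-method
propagation of the parameter CI widths assuming independence — the
published metric CIs were derived by an unstated ratio construction and
are therefore not exactly reproducible; the packaged reference values
retain them verbatim.

**Unfolding.** q(*y*) = exp[*k*₁(*y*/100)^*k*₂ − *k*₃(*y*/100)^(1+*k*₂)]
with *k* ∈ [0, 10]³. The box bound is the sole smoothness control (no
extra penalty); it is what prevents excessively sharp peaks. q(0) = 1
is pinned exactly, including on the *k*₂ = 0 boundary where the
continuum limit would otherwise jump. The predicted metric for each
radiation type is the trapezoid fold of q with that type's *d*-spectrum
on the spectrum's own grid (a `refine_grid` utility exists for
convergence checks); the objective is the CI-width-weighted sum of
squared residuals. The γ-normalizing constant of the underlying
first-kind Fredholm relation is fixed to 1, so only the shape of q is
identified. Minimization runs SLSQP from `n_restarts` (default 300)
uniform-random seeded starts; ties within 1e-8 keep the first-found
solution and the full sorted restart log is retained for multimodality
diagnostics. Goodness of fit is unweighted R² (about the mean observed
metric) and RMSE.

Identifiability caveat: with six observations and three parameters the
optimum can be ridge-like (the TE channel tends to pin *k*₁ at the
upper bound), so recovery is assessed on folded predictions, not on raw
*k* values.

**Prediction.** Any dose-weighted environment spectrum can be folded
with parametric or tabulated weighting functions. Tabulated weightings
interpolate linearly and refuse to extrapolate: the tabulation must
cover the spectrum support. Q̄ is linear in dose-weighted mixtures and
H = D·Q̄ is linear in both factors; both properties are tested.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *statistical structure* the analysis
assumes, at the published study conditions:

- **Tumor counts**: Poisson draws around *M_i(D)* using the published
  best-fit parameters as truth (*T*, *N* per type; *s* = 38.7 Gy⁻¹).
  The background *B* is not published; we use 3.0 tumors/mouse, a
  typical spontaneous intestinal tumor yield for APC^1638N/+ males. An
  overdispersion (negative-binomial) knob is deliberately absent — the
  fitting likelihood is Poisson and the generator matches it.
- **Study design**: group sizes exactly as published (controls 68,
  H 40, He 92, C 60, O 66, Si 136, Fe 90, γ 127); only dose *ranges*
  are published, so the default design places 4–5 doses spanning each
  range (e.g. Si at 5/10/50/100/140 cGy) with mice split as evenly as
  the totals allow. Doses are cGy at the I/O boundary, Gy internally.
- **Spectra**: triangular surrogates and their dose-weighted mixtures
  on a merged grid, each component renormalized so it contributes
  exactly its dose fraction (this makes mixture linearity exact at the
  discrete level). An optional log-normal smearing kernel
  (column-normalized, hence mass-conserving and exactly the identity as
  σ→0) mimics energy-loss straggling.

They do *not* emulate: track-structure physics (secondary particles,
δ-ray escape, the multi-component structure of simulated spectra),
energy depositions from tracks missing the target, target-diameter
dependence, dose-rate effects, or inter-mouse heterogeneity beyond
Poisson. Passing tests therefore demonstrate correctness of the
estimators under the model's own assumptions — parameter recovery, CI
coverage, unfolding self-consistency — not fidelity of the surrogate
spectra to measured ones. Published quality-function parameters, R²/
RMSE values, and environment predictions depend on the unpublished
simulated spectra and raw per-mouse data, and are treated as
qualitative anchors only (shape checks: q ≈ 1 below 5 keV/µm for the
TE channel, rise-peak-flatten behavior with the peak near 50–100
keV/µm, NTE metrics exceeding TE metrics on GCR-like mixtures).

## Numerical choices

- Trapezoid integration throughout; no adaptive quadrature. Exponent in
  q capped at 700 so corner candidates in the k-box produce a
  huge-but-finite objective rather than overflow.
- Poisson mean clamped at 1e-12 inside the log; *B* bounded below at
  1e-8.
- Optimizer tolerances: L-BFGS-B ftol 1e-12 (fit), SLSQP ftol 1e-10
  (unfolding); profile-CI bisection terminates at 1e-4 relative.
- Spectrum TSV writer emits 17 significant digits so adjacent grid
  points one ulp apart survive a round trip.
- Degenerate inputs: all-zero densities, non-monotone grids,
  non-overlapping rebin targets, zero CI widths, fewer than three
  radiation types, and negative doses/LETs are rejected at construction
  with specific errors; 2–3-point rebin targets are allowed with a
  logged warning.
- Problem sizes in the test suite are chosen for fast, stable runs:
  recovery simulations use 100 replicates with 6 fit restarts,
  unfolding self-consistency uses the full 300 restarts, bootstrap
  smoke tests use ~12 resamples.

## Known limitations

- The Poisson likelihood understates uncertainty if real tumor counts
  are overdispersed; CIs would then be anti-conservative.
- Profile CIs assume the χ²(1) asymptotics, which are approximate at
  active constraints.
- The triangular surrogate is known to be biased for light ions (its
  dose means for H and He differ substantially from track-structure
  values), so unfolded functions calibrated on surrogates should not be
  applied quantitatively to real mixed fields.
- No nonparametric or regularized unfolding; channels (TE, NTE) are
  fitted separately, never jointly.
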