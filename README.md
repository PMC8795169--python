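# microq

Microdosimetric radiation quality factors from lineal-energy spectra and
heavy-ion tumor dose–response data.

## The problem

The health risk of a mixed radiation field — such as the galactic cosmic
ray environment in space — is quantified relative to photons through a
quality factor. The microdosimetric approach computes it from the
dose-weighted probability density *d*(*y*) of single-event lineal energy
*y* (energy deposited by one track in a micrometre-scale site, divided
by the site's mean chord length), weighted by an empirical biological
weighting function:

    Q̄ = ∫ Q(y) d(y) dy,        H = D · Q̄

where *H* is the dose equivalent (Sv) for absorbed dose *D* (Gy).
Because *d*(*y*) can be measured continuously in situ with a
tissue-equivalent proportional counter, a calibrated weighting function
turns such a detector into a live biologically-effective-dose monitor.

`microq` implements the full calibration pipeline for one endpoint,
heavy-ion-induced intestinal tumorigenesis in APC^1638N/+^ mice:

1. **Spectra** (`microq.spectra`) — lineal-energy spectrum container,
   the transform *d*(*y*) = *y f*(*y*) / ∫ *y f*(*y*) d*y* and its
   inverse, frequency/dose means, rebinning, TSV I/O, and a triangular
   chord-length surrogate generator with ȳ_F = LET and ȳ_D = (9/8)·LET.
2. **Dose response** (`microq.dose_response`) — per-mouse tumor counts
   modeled as Poisson with mean
   *M*(*D*) = *B* + *T*·*D* + *N*·(1 − e^(−*s·D*)), combining targeted
   effects (TE, linear in dose) and non-targeted/bystander effects
   (NTE, saturating); joint maximum-likelihood fit across radiation
   types with shared *B* and *s*, the constraint *T*_ion ≥ *T*_γ, and
   profile-likelihood or bootstrap CIs. Ratios to the γ-ray reference
   give the low-dose relative effect metrics E_TE = *T*_i/*T*_γ and
   E_NTE = *N*_i/*N*_γ.
3. **Unfolding** (`microq.unfolding`) — the weighting function is
   parameterized as q(*y*) = exp[*k*₁(*y*/100)^*k*₂ − *k*₃(*y*/100)^(1+*k*₂)]
   and fitted to the observed metrics by minimizing the CI-weighted
   objective F = Σᵢ (E_pred,i − E_obs,i)²/CIᵢ² with 300 random-start
   SLSQP searches in the box [0, 10]³.
4. **Prediction** (`microq.prediction`) — folds fitted (or tabulated)
   weighting functions with arbitrary environment spectra to produce
   effect metrics, Q̄, and dose equivalents.
5. **Synthetic data** (`microq.synthetic`) — seed-deterministic
   generators for tumor counts at the published study design, mixture
   spectra, and unfolding problems with known truth.

A `typer` CLI (`microq simulate|fit-dose-response|metrics|unfold|fold|predict|run`)
wraps the library.

## Worked example

```python
from microq import (IonBeamSpec, triangular_spectrum, frequency_to_dose,
                    mean_lineal_energy, QualityFunction, fold,
                    reference_fit, effect_metrics)

spec = frequency_to_dose(triangular_spectrum(IonBeamSpec("Si", let=69.0)))
print(f"Si dose-mean lineal energy: {mean_lineal_energy(spec, 'dose'):.1f} keV/um")

m = effect_metrics(reference_fit())
print(f"E_TE(Si) = {m.te['Si'].value:.2f}, E_NTE(Si) = {m.nte['Si'].value:.2f}")

q = QualityFunction(2.91, 0.34, 0.95, effect_channel="NTE")
print(f"fold(q_NTE, d_Si) = {fold(q, spec):.2f}")
```

prints

```
Si dose-mean lineal energy: 77.6 keV/um
E_TE(Si) = 3.08, E_NTE(Si) = 5.77
fold(q_NTE, d_Si) = 7.09
```

The first line is the (9/8)·LET dose mean of the triangular surrogate
spectrum for a 300 MeV/n Si beam; the second gives the published
relative low-dose effect metrics for Si (TE slope and NTE plateau,
each relative to γ rays); the third folds the published 16 µm NTE
weighting function with the Si spectrum.

The end-to-end synthetic pipeline (simulate tumors → fit → metrics →
unfold both channels → predict a GCR-like mixture):

```sh
microq run --outdir out --seed 3 --restarts 60 --fit-restarts 8
```

writes `out/summary.json` with, e.g., an unfolded NTE channel
(R² = 0.94) and mixture predictions E_TE ≈ 1.29, E_NTE ≈ 2.33 — the
characteristic result that non-targeted effects dominate the low-dose
response to a space-like mixed field. Re-running with the same seed
reproduces the outputs byte-for-byte.

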