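# Methods

This note records the models, conventions and design choices behind
`saffronir`, in the spirit of a statistics package's methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The calibration problem

Three saffron quality indices are modelled from NIR absorbance spectra:
loss on drying (LD, % w/w), total crocin I + crocin II (TCCC, %) and
picrocrocin (CP, %). The reference study conditions emulated throughout are
a bank of 928 samples scanned from 1000 to 2499 nm, split 828/100 into
calibration and verification sets, modelled on the 1050–2400 nm
characteristic band with 8-fold cross-validation. The calibration-set
reference distributions are LD 6.4–11.2 % (mean 8.65, SD 0.91), TCCC
10.0–19.5 % (14.86, 2.00) and CP 7.0–14.8 % (10.54, 1.46).

## Preprocessing operators

All operators act per spectrum (row); operators with train-fitted state
(MSC reference, mean-centering column means) are fitted on calibration data
only and reused verbatim on new spectra. Conventions worth stating because
the literature contains more than one:

* **SNV** divides by the sample (n−1) standard deviation.
* **MSC** regresses each spectrum on (1, reference) by ordinary least
  squares and returns (x − a)/b; the reference is the mean calibration
  spectrum, and the fit is linear (no higher-order variant). |b| < 1e−12 is
  an error.
* **Detrend** subtracts a least-squares polynomial in wavelength
  (default degree 2, the usual SNV–DT pairing), computed on a centred and
  scaled wavelength axis for conditioning.
* **Savitzky–Golay** uses window 11, polynomial order 2 by default for both
  the smoothing and the first-derivative pass (the two passes are distinct,
  applied in that order). Derivatives are divided by the grid step (units:
  absorbance/nm), so results are sampling-independent; a uniform grid is
  required. Edges evaluate the polynomial fitted to the first/last full
  window, so output length equals input length.
* **First difference** is exposed as a forward difference on the midpoint
  grid but is not part of the three canonical pipelines.

Pipelines fit each stateful step on the calibration set *as transformed by
the preceding steps*, then apply it to every set. Serialization (JSON)
round-trips fitted state bit-identically because Python float repr is
exact.

## PLS regression

PLS1 via NIPALS, one model per index (the reference workflow reports
per-index models, so no PLS2). With a single response the NIPALS inner loop
is stationary after one pass; it is retained with tolerance 1e−12 / 500
iterations as a numerical guard. Components deflate both X and y; the
regression vector is W(PᵀW)⁻¹q. Because PᵀW is upper triangular, the
coefficient vectors of all truncated models are recovered from one fit
(`coefficient_path`), which makes the cross-validated SECV curve cost a
single fit per fold.

Latent-variable selection: seeded random partition into k near-equal folds
(default 8), SECV per candidate count, argmin with ties broken toward the
smallest count. The candidate ceiling defaults to min(20, n_train − 1, p).

## Evaluation conventions

* SEC = √(Σe²/(n − LV − 1)) — residual degrees of freedom with intercept.
  SECV = √(Σe²_cv/n). The source material names these statistics without
  formulas; these are the standard chemometric conventions and are a
  documented convention here, not a reproduced fact.
* RPD = 1/√(1−R²) from the calibration correlation, reported to 3 decimals.
* Reliability: *unreliable* if SECV > 1.2·SEC or RPD < 1.4; *reliable* if
  SECV ≤ 1.2·SEC and 1.4 ≤ RPD ≤ 2.0; *optimal* if SECV ≤ 1.2·SEC and
  RPD > 2.0. Bounds are inclusive except the strict RPD > 2.0.
  On clean synthetic data the CV error of a many-component model routinely
  exceeds 1.2× its training SEC even when RPD is enormous, so the verdict
  reads "unreliable" while predictions are excellent; the rule is kept
  verbatim rather than adapted, since it encodes a field convention about
  real, noisy calibrations.
* Outlier exclusion: leverage hᵢ = 1/n + tᵢᵀ(TᵀT)⁻¹tᵢ from the score
  matrix; studentized residual eᵢ/(SEC·√(1−hᵢ)); |t| > 3 flags a sample.
  One pass only: fit → flag → remove → refit (pipeline, LV selection and
  model are all re-estimated on the cleaned calibration set). The
  threshold and single-pass policy are package conventions; the reference
  procedure names the tool but not its parameters. Exactly zero residuals
  are never flagged; hᵢ ≥ 1 flags with infinite studentization.
* The published calibration table contains one internally inconsistent
  cell (the method-3 TCCC RPD duplicates the LD row's value instead of
  following the RPD equation). The constant table in
  `saffronir.evaluate.TABLE2_ROWS` keeps the printed value verbatim; the
  reproduction test asserts the inconsistency rather than silently fixing
  it.

## Synthetic data generator

The generator stands in for the proprietary customs sample bank. Per
sample,

```
clean(λ)   = background(λ) + Σ_c conc_c · Σ_bands amp · N(λ; center, σ)
emitted(λ) = gain · clean(λ) + offset + slope · (λ − λ₀) + ε(λ)
```

* Concentrations are truncated normals matching the reference
  distributions above (plain normal draws with rejection).
* The eight Gaussian bands sit at the absorptions visible in saffron NIR
  spectra (1200, 1380, 1450, 1580, 1700, 1950, 2100, 2300 nm). Assigning
  them to constituents — water/volatiles (LD) on the 1450/1950 nm O–H
  bands, crocins on 1200/1700/2300, picrocrocin on 1380/1580/2100 — is a
  fixed modelling convenience so tests are stable, not a chemical claim.
* Instrument artefacts: gain ~ U[0.85, 1.15], offset ~ U[−0.05, 0.05],
  baseline slope ~ U[−2e−5, 2e−5] per nm, iid Gaussian noise with
  SD 0.002 absorbance.
* The fixed matrix background (ramp + broad curvature + water humps,
  roughly 0.5–2 AU) deliberately dominates the wavelength-variance of the
  mean spectrum. This is both physically sensible for plant powders and a
  structural requirement of the scatter model: MSC estimates its gain by
  regressing each spectrum on the mean spectrum, and that estimate
  identifies the scatter gain (rather than the chemistry) only when the
  shared background carries most of the reference's variance. Band
  amplitudes (0.0035–0.015 AU per % constituent) were chosen once so that
  scatter corruption visibly degrades an uncorrected PLS model and MSC/SNV
  recover the bulk (≥ 80 % on the fixed test seeds) of that degradation —
  the property that makes the three-pipeline comparison meaningful on
  synthetic data — and are not revisited.
* Indices are drawn independently (no covariance information is available
  for the real bank).

What the generator does **not** emulate: wavelength-dependent (non-flat)
scatter, instrument line-shape and detector nonlinearity, band overlap
structure of real saffron constituents, inter-index correlations, and any
matrix variation between origins or harvest years. Passing tests therefore
demonstrate the correctness and internal consistency of the workflow, not
field performance on real saffron.

## Scale choices in tests

Test problem sizes are chosen as the smallest that make each property
sharp: operator identities run on toy matrices; the NIPALS/reference
cross-check uses fifty 20×50 problems; scatter-realism uses 400-sample
sets over three fixed seeds; outlier recovery injects a +10·SEC response
error into 400-sample calibrations over twenty seeds; the end-to-end
accuracy check runs the full 928-sample simulation once; distribution
emulation samples 200 seeds of concentrations only (the spectra are
irrelevant to that check). The held-out R² > 0.85 bound for the full-scale
run is the qualitative regime of the reference calibration; the synthetic
bank is cleaner than real customs samples, so the achieved R² is higher.

## Known limitations

* PLS1 only; no PLS2, kernel or sparse variants, and no uncertainty
  intervals on coefficients or predictions.
* No wavelength resampling: all sets must share one grid.
* The studentized-residual pass is single-shot; iterative re-screening can
  flag additional samples on heavily contaminated data.
* Negative predicted concentrations are reported as-is with a warning,
  never clipped.
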