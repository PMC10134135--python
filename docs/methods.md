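# Methods

## The descriptive generative model

`irsim` treats an absorbance spectrum of a molecularly complex sample as a
Gaussian linear outcome on a fixed wavenumber grid (p features, cm⁻¹):

```
Y = b̄ + Σᵢ₌₁..ₘ βᵢ sᵢ + ε,   sᵢ = bᵢ − b̄,   βᵢ ~ N(0, σ_β²) i.i.d.
```

calibrated from m reference spectra b₁..bₘ of one molecular state. The
motivation is the linearity of infrared absorbance in concentration: a
complex spectrum is a concentration-weighted sum of single-component
spectra (the *bottom-up* picture, also implemented as
`simulate_bottom_up`). Since component libraries for complex biofluids do
not exist, the *descriptive* model replaces the unknown component basis
with measured whole-sample spectra, whose centered versions span the
empirical directions of biological variability.

Calibration fixes the two free statistical quantities:

* the coefficient means are absorbed into the mean spectrum (μᵢ = 0 after
  centering), so E(Y) = b̄ exactly;
* σ_β² = 1/(m−1) makes the model's per-feature variance
  σ_β² Σᵢ sᵢⱼ² equal the cohort's **unbiased** sample variance — an exact
  algebraic identity, checked to 1e−10 relative in the tests. Unbiased
  (ddof = 1) estimators are used consistently, including for the noise
  calibration below.

The β are drawn i.i.d. per simulated spectrum and per calibration vector.
Real molecular concentrations are correlated; no explicit dependency
structure is added because the centered basis already carries the empirical
covariance of the pool (the simulated covariance is exactly the reference
sample covariance).

**Measurement noise** is additive, white and Gaussian, ε ~ N(0, diag(σⱼ²)),
with σⱼ the per-wavenumber ddof-1 standard deviation across ≥ 2 replicate
blank (water) measurements. This is the dominant noise type of FTIR
measurements; multiplicative noise and baseline-drift vectors are outside
scope, as are non-Gaussian β or δ distributions.

**Class differences.** In two-pool mode the case state gets its own
calibrated model from independent case measurements. In discriminant mode a
case spectrum is a control draw plus δ·d, with d the differential
fingerprint (case mean − control mean) and δ ~ N(μ_d, σ_d²). How μ_d and
σ_d should be calibrated is application-specific and not prescribed here;
they are required arguments with defaults μ_d = 1, σ_d = 0 (apply the mean
difference deterministically).

**Scale factors.** `beta_scale` and `eps_scale` multiply *standard
deviations*, not variances: `beta_scale = 0.5` means the within-person
regime in which biological variability is about a factor 2 below the
between-person level; `eps_scale = 0` removes measurement noise.

**Molecular complexity.** `subsample_basis` restricts a model to m randomly
selected calibration vectors while keeping the mean spectrum constant, so
complexity changes never touch the class signal directly — added complexity
only masks it. A paired call draws disjoint index sets for the case and
control models (2 × m distinct source vectors in total). By default the
reduced model recalibrates σ_β to 1/√(m_subset − 1); the complexity sweep
instead *pins* σ_β at the full-pool value, holding the strength of
biological variability constant while its structure is thinned.

## Classification pipeline

Binary case-control classification uses an L2-regularized logistic
regression (scikit-learn, lbfgs, tol 1e−6) on per-training-fold z-scored
features, evaluated by stratified k-fold cross-validation repeated with
reshuffling; the summary is the ROC-AUC mean and ddof-1 standard deviation
over all k·repeats folds. The penalty is fixed (inverse strength C = 1.0 by
default) rather than tuned: the ridge model is used for robustness to
noise, and sensitivity can be probed through the `penalty_strength`
argument. ROC-AUC is computed by the Mann–Whitney mid-rank formula (ties
count ½), which makes the antisymmetry `auc(s) + auc(−s) = 1` exact; the
averaged ROC curve for reporting is vertically averaged on a fixed
101-point FPR grid (this affects plots only, never the AUC).

`train_sim_test_exp` implements the strictest validation protocol: the
reference cohort is split into stratified folds, class models are
calibrated on the *remaining* spectra only, classifiers are trained purely
on cohorts simulated from those models and tested on the held-out fold. A
hard leakage guard aborts if a held-out sample id ever reaches calibration.

## Randomness and reproducibility

Every stochastic operation takes an integer seed and derives independent
child streams via `numpy.random.SeedSequence(seed, spawn_key=path)`, where
the path encodes (arm, grid cell, replicate, …). Streams are a pure
function of (seed, path), so results are independent of execution order and
sweeps could run cells concurrently with byte-identical output; execution
here is serial. Same seed ⇒ bit-identical cohorts and fold splits. Each
sweep replicate redraws everything below it — the cohort, the noise
realization and (in the complexity sweep) the basis subsets.

## The synthetic reference generator

`fixtures.generate_reference_cohorts` emulates exactly the statistical
structure the descriptive model assumes, with known ground truth — no more:

* a smooth mean spectrum: Gaussian bands at serum-typical positions
  (amide-I/II-like bands near 1650/1545 cm⁻¹, CH-bending and carbohydrate
  bands below); positions are cosmetic defaults;
* per-class banks of r smooth random component vectors (low-pass-filtered
  white noise, Gaussian kernel σ = 3 grid points, unit-RMS-normalized to
  `component_rms`), with i.i.d. N(0, bio_sd²) subject weights;
* a fixed smooth class-difference vector, `signal_amplitude` × unit-RMS,
  added to every case — drawn from the same smoothing process as the
  components, i.e. a band-limited molecular signature lying mostly inside
  the span of biological variability;
* additive white noise of standard deviation `noise_sd` on every spectrum,
  and blanks = pure noise around a flat baseline.

Defaults: 201 features on 950–1750 cm⁻¹ (4 cm⁻¹ step, the protein-rich
fingerprint window), r = 200 components per class (so complexity
subsampling up to 2 × 100 disjoint vectors is possible), 523 subjects per
class and 100 blanks. `noise_sd` defaults to a 10% variance share of the
per-feature biological variance: large enough that measurement noise
measurably degrades classification near the operating point, small enough
that biological variability dominates — the regime reported for FTIR serum
fingerprinting, where eliminating measurement noise yields a few points of
AUC while halving biological variability yields ten.

What the generator does **not** emulate: physically accurate band shapes,
baseline drift, scattering artifacts, correlated (non-white) instrument
noise, non-Gaussian population structure, or matched-pair sampling. Tests
passing on these fixtures therefore demonstrate the *statistical* machinery
(calibration identities, moment recovery, protocol validity, monotone
responses to the model parameters), not agreement with any particular
instrument's data.

`tune_signal_to_auc` finds the signal amplitude at which simulated cohorts
cross-validate at a target AUC (e.g. 0.88, the group-level regime) by
bisection. Every evaluation reuses the same derived random streams (common
random numbers), making the evaluated AUC a deterministic, monotone
function of amplitude; monotonicity across evaluated points is asserted
(0.5 × tol slack for residual Monte-Carlo jitter). One subtlety: at zero
amplitude the evaluated AUC is *not* 0.5, because two-pool calibration
bakes the chance difference of the two sample means into the class models
and the simulation reproduces it as real signal (Mahalanobis size ≈ 2p/n).
The bracket is nevertheless valid for targets above that floor (~0.7 at
p = 201, n = 523); true null behavior is exercised through the
zero-discriminant path, where both arms share one model.

## Numerical choices

* **Exact reconstruction.** The contract that mean + basis row reproduces
  every calibrating spectrum bit-for-bit cannot be met by a single IEEE-754
  addition (near cancellation the representable sums are quantized coarser
  than the target value), so the model stores the exact residual of that
  addition — bounded by one ulp of the spectrum — and
  `DescriptiveModel.reconstruct()` re-adds it (compensated summation).
* **Grids.** Wavenumber-grid compatibility is strict float equality; no
  resampling or interpolation anywhere, keeping calibration
  bit-reproducible. Incompatible grids raise instead.
* **Non-negativity.** None imposed: the model is linear-Gaussian, centered
  basis vectors and simulated absorbances may be negative. Bottom-up
  concentrations are not truncated at zero; a warning is logged when a
  component's negative-concentration probability exceeds 1%.
* **Degenerate inputs.** Calibration requires m ≥ 2 (single spectra have
  undefined variability), noise calibration ≥ 2 replicates, CV requires
  every class to have ≥ k members; identical replicates yield a zero noise
  vector and identical spectra a zero basis, both valid.
* **io.** Cohort CSVs store floats at `repr` precision and are read back
  with round-trip float parsing, so write→read is lossless; all file writes
  are atomic (temp file + rename).

## Problem sizes used in the shipped analyses

The validation, sweep and acceptance analyses run at the reference scale of
523 + 523 spectra on 201 features with 10 simulated datasets (or
replicates) × 10 folds per condition — 100 fold-level AUCs per reported
mean, matching the repeated-CV budget used for the headline numbers. The
example scripts and unit tests use smaller cohorts (60–300 spectra, ~60
features) chosen so each property remains decidable within Monte-Carlo
error at desk scale. Large-training-set analyses beyond ~20,000 simulated
spectra are out of scope.

## Null-band checks

The cross-validated AUC of a *single* null dataset is not tightly pinned to
0.5: all folds share that dataset's chance separability, whose scale is
roughly 0.6/√n. Null checks therefore average over several independently
simulated datasets (as the validation protocol does for its 10 datasets)
before asserting the [0.45, 0.55] band.

## Known limitations

* The descriptive model reproduces first and second moments of the
  reference cohort; higher-order structure (skewness, mixture
  substructure, batch effects) is not modeled.
* Calibration vectors contain the reference measurement noise, so
  simulated spectra carry reference noise *plus* fresh simulated noise —
  a small variance inflation (≈ 5% at the default 10% noise share),
  accepted for fidelity to the calibration-from-measurements design.
* Complexity-threshold values (the m at which separation stops being
  perfect) depend on the correlation structure of the calibration vectors,
  the spectral bandwidth and the resolution; they transfer across
  applications only qualitatively.
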