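# Methods

## Scope and data model

The package analyses Vis-NIR reflectance spectra of individual berries on
a fixed wavelength grid (default 400–1000 nm at 5 nm, 121 bands) with one
ordinal defect label per fruit: sound(1) < mild(2) < moderate(3) <
severe(4). The default population mirrors a realistic grading outcome with
strong class imbalance: 51/182/285/107 fruit (625 total). The two-class
problem collapses ranks 2–4 into "defective".

## Synthetic data generator

No spectra are deposited for this task, so the generator is a first-class,
tested component, not a fixture. It emulates:

* **Base curve** — a smooth fixed template (logistic red-edge plus Gaussian
  absorption dips near 760 and 970 nm), since only band–chemistry
  associations are known, not measured spectra.
* **Severity** — one latent severity score per fruit,
  z ~ Normal(rank − 1, `severity_sd`=0.45). Adjacent classes overlap, so
  misclassification concentrates on neighbouring grades. Three chemistry
  regions respond to z with *monotone but distinct* curves: carotenoid
  loss saturates early (1.5·tanh(z/1.5), reflectance rises over 400–680 nm),
  water status drifts linearly (deeper absorption near 732 nm), and
  sugar-linked changes onset late (smooth hinge at z = 1.5; dips at
  820/930/970 nm). The distinct response shapes are essential: if all
  regions responded linearly the class means would be exactly collinear,
  and the argmax rule on linear indicator regression then provably never
  predicts the middle (and, under imbalance, the rare extreme) classes —
  the classical "masking" degeneracy, which real spectra do not exhibit.
* **Artifacts** — per-spectrum multiplicative gain (log-normal,
  `scatter_sd`=0.06) and additive baseline (Normal, `baseline_sd`=0.015),
  exactly the distortions MSC removes; plus independent per-band noise
  (`noise_sd`=0.003). Default effect sizes are 0.080/0.060/0.060
  reflectance units per severity step for carotenoid/water/sugar. These
  defaults were calibrated once against the property suite (the only
  available constraint, since no within-class variance or SNR is published)
  so that the four-class confusion matrix is near-tridiagonal with
  realistic diagonal magnitudes; they are not fitted to any measured data.
* **Hypercubes** — elliptical fruit on a dark background with gentle radial
  shading, a contiguous darker defect patch (only on fruit of severity ≥
  mild, covering a configurable fraction of the fruit area), and glare
  pixels saturated at the 1.05 reflectance ceiling in all bands. Diffuse
  pixels are capped at 0.96 so saturation identifies glare unambiguously.
  Truth masks (background / sound tissue / defect tissue / glare) are
  returned for every rendered scene.
* **Planted-band mode** — for variable-recovery experiments,
  `informative_bands` puts the class effect at exactly those band indices.
  Each planted band draws its own within-class latent deviation (shared
  class mean, independent noise) and the three response families cycle
  across the bands; both choices make each band carry partly independent,
  non-collinear class information, so "how many planted bands were
  recovered" is a well-posed question. `recovery_scenario()` freezes this
  configuration (10 bands, effect 0.08, `severity_sd` 0.6, noise 0.01, no
  scatter/baseline, 4 × 50 fruit).

Determinism: everything flows from one `numpy` Generator seeded by the
config; identical seeds give bitwise-identical output on any platform with
IEEE doubles.

What the generator does *not* emulate: instrument response and wavelength
calibration error, spatially correlated noise, touching fruit, class-
dependent scatter, or the full diversity of real defect chemistry. Passing
tests therefore demonstrate correctness of the *algorithms* and the
qualitative error structure, not field performance on real berries.

## Extraction

Segmentation thresholds a single reference band (default 800 nm, on the
NIR plateau where fruit/background contrast is highest in the generator)
and takes 8-connected components above a minimum area, ordered row-major
by centroid; a component covering more than half the frame is flagged
oversized. Glare exclusion removes pixels at or above `saturation_level`
(default 0.98) in *any* band. Optional defect-edge exclusion removes
pixels whose spatial gradient magnitude (per band, averaged over bands)
exceeds a threshold; it is off by default, so the default mean spectrum
averages all non-glare fruit pixels — whether defect pixels belong in the
average is genuinely ambiguous, so both behaviours are provided. The mean
spectrum is the arithmetic band-wise mean over retained pixels. Pixel-wise
classification pushes every retained pixel through the model's frozen
pipeline and discriminant rule; background and excluded pixels get the
null label 0.

## Pre-processing

* SNV standardises each row with the sample (n−1) standard deviation.
* MSC fits each row against a reference by least squares, x ≈ a·ref + b,
  and returns (x − b)/a; the reference is the training-set mean spectrum
  (the standard convention).
* Savitzky–Golay derivatives (default window 15, polynomial order 3,
  2nd derivative) are scaled by 1/spacing^deriv so loadings are per nm and
  comparable across grids; the constant scale does not affect
  classification. Edge policy: truncate (window−1)/2 bands per end
  (default), keeping every output column identified with one wavelength;
  an alternate `edges="polyfit"` mode keeps all bands via edge refits.
* Mean centering is always the last step when present.

`fit_pipeline` learns all statistics from training rows; `transform`
applies them frozen, so the inner-CV contract (no test-set leakage) holds
by construction and is asserted by tests.

## PLS-DA, PCA, CovSel

PLS2 is the iterative bilinear (NIPALS) variant with X-score deflation:
it is deterministic (the Y-column with the largest sum of squares seeds
each component; there is no random initialisation), its components are
nested (coefficients for any smaller number of latent variables come from
the same fit, which the inner CV exploits), and at full rank it reproduces
least squares exactly. Class assignment is argmax over predicted
responses; exact ties resolve to the lower severity rank. An optional
prior-correction mode (subtract the training class priors before argmax)
mitigates rare-class shrinkage under imbalance but is off by default,
since the study applied no reweighting. Component signs are oriented so
the highest-severity training class scores at least as high as the lowest
on every latent axis, which makes canonical scores averageable across
resampled fits.

PCA is a thin SVD of the centred matrix. CovSel operates on column-centred
X and Y; the criterion Σₖ(xⱼᵗyₖ)² is the squared covariance up to a
constant factor that cannot change the argmax. Deflation projects both
blocks orthogonally to the chosen column; if the criterion or the deflated
X vanishes numerically (relative threshold 1e−24 on the product of block
sums of squares) selection stops early with a warning and a shorter list.

## Repeated double cross-validation

Partitions are stratified by class (the 51-vs-574 imbalance would
otherwise regularly strip the sound class from folds); each class's
shuffled members are dealt round-robin into segments. One master seed
spawns independent per-run substreams (`numpy` SeedSequence), so results
depend only on (data, config, seed). The inner loop aggregates one
confusion matrix per candidate (pipeline, subset size, latent count)
across the inner folds and minimises the macro error — the mean per-class
error rate, matching the reported "Error (%)" convention; ties break to
fewer latent variables, then fewer variables, then the earlier pipeline.
CovSel runs once per fold to the maximum requested size and the nested
prefixes are evaluated, as are the nested latent counts within a single
PLS fit. The winning configuration is refit on the full outer-training
set and the held-out segment predicted. When the candidate grid is a
single combination with selection disabled, the inner loop is skipped as
an optimisation — it could not change the choice, and outer refits still
happen, so model counts remain measured quantities.

Selection frequency of a wavelength = (models whose subset contained it) /
(runs × outer segments); the stable subset is the set at or above the
threshold (default 0.8), sorted by wavelength. The confirmation run
(`rdcv_on_subset`) restricts the *preprocessed* matrix to the subset —
derivative filters need the contiguous full spectrum, and selection in the
engine likewise operates on preprocessed variables — and disables
selection. Per-sample mean canonical scores carry a 95 % confidence
half-width of 1.96·std/√n_runs across runs.

## Metrics and reporting

Accuracy is trace/total, algebraically identical to the class-count-
weighted mean of per-class sensitivities (asserted on random matrices);
the "error" column is the macro mean of per-class error rates, which is
*not* 100 − accuracy under imbalance. Aggregation over runs reports the
element-wise mean and sample (n−1) standard deviation, zero for a single
run. Displayed percentages round half-away-from-zero to one decimal;
internal values keep full precision. Tables are tab-separated text in the
per-class layout; plots (PCA scores, mean canonical scores with CIs,
selection frequency with stable wavelengths marked) are PNG via the Agg
backend.

## Problem sizes used by tests and the acceptance script

Simulation experiments run at reduced repetition counts chosen as the
smallest sizes at which the checked properties are stable: the 500-model
count uses the full 10 × 50 scheme on a 200-sample set with a single
candidate configuration; the label-permutation null and the qualitative
confusion-structure check use 10 and 5 runs; planted-band recovery uses
5 runs × 10 outer splits. Oracle equivalences run on toy matrices
(10 × 4, 20 × 8, 40-band rows) where the independent computation is exact.

## Known limitations

* With the study's imbalance and the default argmax rule, the sound class
  is systematically under-predicted in the synthetic four-class problem
  (its indicator regression is dominated by the three-times-larger mild
  class); the real study reports much higher sound sensitivity, implying
  class structure in real spectra beyond what a one-dimensional severity
  model provides. The prior-correction option recovers sound sensitivity
  at the cost of overall accuracy.
* The two-class decision uses argmax (equivalent to a 0.5 cut on two
  responses); alternative canonical-score thresholds are exposed only
  through the score outputs, not as decision rules.
* ENVI support covers the common regular layouts (bsq/bil/bip, numeric
  types 1/2/3/4/5/12, little-endian, header offset 0) — enough for
  round-tripping this pipeline's cubes, not a general ENVI reader.
* The stable-subset size is a data-dependent outcome of the selection
  procedure, not a target; different seeds legitimately give different
  subset sizes.
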