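# Methods

`hsfluor` implements a quantitative analysis chain for wide-field
hyperspectral fluorescence images of 5-ALA-labeled brain tumor biopsies:
spectral unmixing into five fluorophore abundances, class-conditional
statistics, and supervised classification of clinically relevant labels.
Because the patient measurements this kind of analysis targets are private,
the package ships a first-class synthetic cohort generator; everything
downstream is exercised and validated against it.

## Signal model and unmixing

An emission spectrum is measured over the visible range 420–730 nm. The
canonical internal grid has 310 bands at 1 nm (420–729 nm); instrument grids
with coarser steps (a liquid-crystal tunable filter sweeps in 3–5 nm
increments) are resampled onto a common grid by linear interpolation with
clipping at zero. The interpolation scheme is a package choice; nothing in
the acquisition physics pins it down, and the basis loader accepts any
tabulated endmember set so alternatives can be substituted.

Each background-corrected spectrum `y` (length 310) is modeled as a
non-negative linear combination of five endmember spectra stacked as columns
of `B` (310 × 5): the two photo-states of protoporphyrin IX — PpIX634 and
PpIX620, peaking near 634 and 620 nm — and the autofluorophores NADH,
lipofuscin and flavins. Abundances solve

    c = argmin_c ½‖y − B c‖²,  c ≥ 0,

via active-set non-negative least squares (`scipy.optimize.nnls`). The
solution satisfies the KKT conditions with a scale-free tolerance
(1e-10 · ‖Bᵀy‖∞ in the tests); on random small instances the objective is
verified against an exhaustive oracle that solves unconstrained least squares
on every one of the 2⁵ support sets and keeps the best feasible solution.
Useful consequences that are tested as properties: unmixing is positively
homogeneous (`unmix(αy) = α·unmix(y)`), noiseless mixtures are recovered
exactly, and appending a basis column can only decrease the residual.

### Synthetic endmember shapes

The true endmember spectra are laboratory-characterized curves that are not
tabulated here, so the default basis is parametric: skew-normal peaks,
re-located so the mode sits exactly at the nominal center, peak-normalized by
default (area normalization is available). Defaults: PpIX634 634 nm / 20 nm
FWHM, PpIX620 620 nm / 25 nm FWHM, NADH 460 nm / 100 nm, flavins 525 nm /
80 nm, lipofuscin 570 nm / 120 nm. The PpIX peak positions are physically
established; the autofluorophore centers and widths are literature-typical
stand-ins. A CSV loader (`wavelength_nm,PpIX634,PpIX620,NADH,lipofuscin,
flavins`) lets measured endmembers replace the synthetic ones without
touching anything downstream. The default basis is well-conditioned
(condition number ≈ 4), which is why noiseless recovery is numerically exact.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at two
granularities.

**Abundance model.** Class-conditional abundances are log-normal with a
shared per-biopsy random effect:
`log c = μ_class + b + ε`, `b ~ N(0, σ_b² I)`, `ε ~ N(0, diag(σ²))`, with
defaults σ = 0.3 and σ_b = 0.15 per log-unit. Log-normality gives strictly
positive, right-skewed intensities; the biopsy effect models acquisition- and
patient-level variation shared by all spectra of one sample. Class means are
`μ_class = μ₀ + Δ·offset_class`: the separability knob Δ scales every
between-class difference, so Δ = 0 is an exact null (all classes share one
distribution) and Δ = 2 is near-separable. The margin, grade and IDH offsets
encode the expected biology (PpIX abundance rises with tumor content and
grade while autofluorescence relatively falls); the twelve tissue-type
offsets are synthetic stand-ins chosen to be mutually spread out. None of
these vectors is calibrated to patient data — synthetic accuracies
characterize the protocol, not the clinical task.

**Geometry and rosters.** A biopsy is a disk of 4–10 mm diameter (190–476 px
at 47.62 px/mm; triangular distribution with mode 288 px ≈ 6 mm) whose
non-overlapping 10 × 10 px tiles fully inside the disk become block spectra —
a 6 mm biopsy yields ≈ 590 blocks, inside the expected 100–1000 per-biopsy
range. Default per-class biopsy counts follow the published cohort (margin
ST 131 / IZ 57 / RABT 100; grades I 9 / II 84 / III 57 / IV 421; IDH mutant
126 / wildtype 285; twelve tissue types from PA 5 to GB 410) and are fully
configurable.

**Cube rendering.** For the image-level pipeline, a phantom's per-pixel
log-abundance field is mean + biopsy effect + σ · (unit-variance
Gaussian-filtered white noise, correlation length 20 px) — a smooth-field
stand-in for unknown within-biopsy spatial correlation. The acquisition
triplet is: blue cube = illumination · B·c(pixel) + dark offset + noise over
tissue (glass background carries no fluorescence; an optional fluid artifact
is a bright, spectrally broad blob adjacent to the tissue); dark cube =
offset + read noise; white cube = flat reflectance reference. The sensor
model is Gaussian read noise (sd 2 counts) plus a Gaussian approximation of
shot noise with variance = 0.5 · signal, and a 100-count dark offset — a
standard sCMOS parameterization. The default illumination scale of 500
counts per unit abundance represents the long (500 ms) exposure; dual-band
normalization cancels it downstream. Cubes default to float32; exactness
checks use float64 rendering, where the noiseless
simulate → preprocess → unmix round-trip reproduces block-mean abundances to
~1e-15 (asserted at 1e-6).

**Dataset-level shortcut.** Classification-scale datasets draw block-level
abundances directly from the same log-normal model (iid per block given the
biopsy effect) instead of rendering ~600 cubes. The cube path is validated
end-to-end separately; the shortcut trades the smooth spatial field for
speed, which matters only to the `pixels_per_sample` feature — neighboring
blocks in a rendered cube are more correlated than iid draws, so the
dataset-level benefit of concatenating neighbors is, if anything,
understated.

## Preprocessing

* **Dark correction**: blue − dark, clipped at zero.
* **Segmentation**: Otsu threshold on the band nearest 634 nm, morphological
  opening (radius-2 disk), then retention of the largest connected component
  (`exclude_artifacts=True`, the default), which drops bright disjoint fluid
  splashes even though they exceed threshold. This is a documented stand-in
  for an unspecified interactive routine; the method tag is stored in the
  mask for provenance. On phantoms with tissue/background contrast ≥ 5 at
  634 nm, recall is ≥ 0.95 (tested).
* **Block extraction**: non-overlapping 10 × 10 tiles anchored at the mask
  bounding-box origin (0-based, half-open coordinates); a tile is kept only
  if fully masked. Every spectrum is a disjoint region, hence an independent
  data point.
* **Dual-band normalization**: each block spectrum is divided by
  √(R̄_a · R̄_b), the geometric mean of its own tile's dark-corrected
  white-light reflectance averaged over two windows (defaults 460–480 nm and
  620–640 nm — an autofluorescence window and the PpIX window). The exact
  published two-band procedure is not reproduced here, so this operation is a
  swappable strategy with the key invariance built in: a uniform illumination
  rescaling applied to both the fluorescence and the white reference cancels.
  The per-block divisors are retained so abundances can be mapped back to raw
  count units. Whether normalization should act per pixel or per block is
  not determined by the source material; per block is the package's choice
  and keeps block means exact.

## Statistics

**PCA variance explained** is Σ of the n largest covariance eigenvalues over
total variance, computed on mean-centered data (scikit-learn PCA, full SVD)
and cross-checked against a direct `eigvalsh` of the sample covariance to
1e-10. Constant data raises (zero total variance). On noiseless
five-fluorophore mixtures, five components explain exactly 100% — the
rank-5 identity that motivates treating the five fluorophores as a
sufficient representation. t-SNE (seeded, PCA initialization) is provided
for visualization only and never feeds classification.

**KS battery**: for every fluorophore and unordered class pair, a two-sample
Kolmogorov–Smirnov test of the null that the two classes' abundances share a
distribution, at α = 0.01 with no multiple-testing correction by default
(raw pairwise p-values are the reporting convention here; Bonferroni/BH can
be applied to the exported long table). `scipy.stats.ks_2samp` with
`method="auto"` uses the exact small-sample null and the asymptotic
Kolmogorov distribution otherwise; the exact mode is verified against full
permutation enumeration on a 3-vs-3 example. Sample sizes may differ between
classes. All spectra are pooled per class, which ignores within-biopsy
clustering: under a Δ = 0 null with clustered data the battery over-rejects
relative to its nominal level (visible in `analysis/03`), so borderline
p-values on pooled spectra should be read cautiously. Type-I calibration at
the nominal level holds for independent samples (rejection rate ≈ 0.005–0.012
at α = 0.01 over 2000 replicates of n = 200 vs 200).

## Classification protocol

Features are abundance vectors of 1–3 blocks concatenated
(`pixels_per_sample`; neighbors are the anchor's nearest disjoint tiles of
the same biopsy by Euclidean tile distance, ties broken row-major). Classes
are balanced to exactly `samples_per_class` anchor draws without replacement,
uniformly over blocks; a class with fewer blocks than that is excluded, and
fewer than two surviving classes is an error. Published dataset-variant
grids are preserved: pixels per sample ∈ {1,2,3}; samples per class
{300,500,800} (tissue type), {1000,3000,5000} (margin), {500,1500,3000}
(grade), all-available (IDH). For tissue type, the WHO-2021 revision maps
(AA, IDH-wildtype) → GB before training, and anaplastic ependymoma can be
excluded by flag.

The split is 80/20, stratified by class. Pooled (per-spectrum) splitting is
the default reading of "each data point is independent"; a biopsy-grouped
split is provided because pooled splitting lets models exploit the shared
per-biopsy effect — blocks of one biopsy on both sides of the boundary act
as a fingerprint. Under the exact null this leakage shows up as test
accuracy a few points above 1/K, still inside the chance band at the tested
sizes; the grouped mode removes it at the cost of approximate stratification.

Model selection ranks every (algorithm, hyperparameter) combination by mean
5-fold stratified CV accuracy on the training set (ties: fewer parameters,
then registration order), refits the winner on the full training set, and
evaluates once on the test set: accuracy, per-class one-vs-rest ROC from the
model's class scores, macro-averaged AUC (the one-vs-rest macro scheme is the
package's choice where the averaging convention is unspecified), and a
confusion matrix. The full grid mirrors the published table — random forests
(5 tree counts × 3 criteria × 3 min-split × 3 max-features), KNN (4×2×2),
SVM (4 kernels), MLP (1–3 hidden layers × 4 widths × Adam/LBFGS, ReLU,
momentum 0.9), AdaBoost (50 estimators, learning rate 1.0) — 180
combinations; our enumeration is reported rather than the source's stated
model count, which its printed grid does not reproduce. The AdaBoost
`SAMME.R` variant no longer exists in current scikit-learn and is therefore
not a grid axis. A `compact_grids()` subset (2 forests, KNN, 1 MLP) is used
by demos, tests and the acceptance script so runs stay in seconds-to-minutes;
MLP iterations are capped at 400 with convergence warnings suppressed during
CV.

## Reproducibility

Every stochastic step takes a seed. Pipeline runs derive stage seeds from
the global seed as `SeedSequence([seed, stage_index])` (kept below 2³¹),
write every artifact with SHA-256 checksums into `manifest.json`, and
re-running an archived config reproduces identical checksums (asserted in the
tests). Cube triplets are stored as band-interleaved multi-page TIFFs with a
JSON sidecar (grid, phase, exposure 500 ms, 47.62 px/mm, seed, labels);
spectra and reports are CSV/JSON.

## Problem sizes

Full-frame acquisition (2048 × 2048 × 310) is supported by the data
structures, but the shipped analyses, tests and acceptance script render
cubes at 256–512 px fields on a 5 nm (63-band) grid with the basis resampled
consistently, and classify cohorts of up to the published roster sizes at
compact hyperparameter grids. These sizes are the package's own choice of
desk scale; all invariants they exercise are size-independent.

## Known limitations

* Synthetic class separations are not calibrated to patient data; absolute
  synthetic accuracies say nothing about clinical performance.
* The smooth-field spatial model and iid block shortcut bracket, but do not
  reproduce, real within-biopsy correlation.
* Segmentation is a thresholding stand-in; heavily fragmented or very dim
  tissue can fall below the Otsu split.
* Pooled KS testing and pooled splitting both ignore biopsy-level clustering
  (quantified above; grouped alternatives provided).
* The emission model is purely linear — no scattering, absorption,
  photobleaching kinetics, or wavelength-dependent reflectance.
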