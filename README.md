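# hsfluor

Quantitative analysis of wide-field hyperspectral fluorescence images of
5-ALA-labeled brain tumor biopsies: spectral unmixing into five fluorophore
abundances, class-conditional statistics, and machine-learning classification
of clinically relevant labels (tissue type, tumor margin, WHO grade, IDH
mutation status).

Malignant glioma resections guided by 5-aminolevulinic acid rely on the red
fluorescence of protoporphyrin IX (PpIX), but autofluorescence from NADH,
flavins and lipofuscin overlaps the PpIX emission range and low-grade tissue
often fluoresces too weakly to see. Hyperspectral imaging resolves this: an
emission spectrum `y` measured over 420–730 nm (310 bands) is decomposed over
five known endmember spectra — the PpIX photo-states PpIX634 and PpIX620 plus
the three autofluorophores — stacked as columns of a 310 × 5 matrix `B`, by
non-negative least squares:

    c = argmin_c ½‖y − B c‖²,   c ≥ 0.

The abundance vector `c` is the quantitative optical biomarker everything
downstream consumes. The package is aimed at researchers building or
evaluating such pipelines; since the underlying patient data are private, it
ships a synthetic cohort generator with the same statistical structure
(log-normal class-conditional abundances with per-biopsy random effects,
realistic biopsy geometry and sensor noise), so the whole chain is testable
and reproducible from a seed.

## What's inside

| module | contents |
|---|---|
| `hsfluor.spectral` | wavelength grids, synthetic/CSV endmember bases, NNLS unmixing |
| `hsfluor.simulate` | class profiles, biopsy phantoms, illumination-triplet cubes, cohort datasets |
| `hsfluor.preprocess` | dark correction, 634 nm segmentation, 10×10 block spectra, dual-band normalization |
| `hsfluor.stats` | PCA variance explained, t-SNE, pairwise two-sample KS battery |
| `hsfluor.classify` | balanced feature tables, 80/20 split, 5-fold CV grid ranking, ROC/AUC evaluation |
| `hsfluor.pipeline` / `hsfluor.cli` | seeded end-to-end runs with manifests, figures, `hsfluor` CLI |
| `analysis/` | numbered drivers reproducing the full analysis on synthetic cohorts |

## Worked example

Unmix a noisy mixture against the default basis:

```python
import numpy as np
from hsfluor import FLUOROPHORES, build_synthetic_basis, unmix_nnls

basis = build_synthetic_basis()                       # 310 x 5, peak-normalized
rng = np.random.default_rng(0)
c_true = np.array([2.0, 0.8, 0.5, 0.3, 0.4])          # strong PpIX634 signal
y = basis.matrix @ c_true + rng.normal(0, 0.01, 310)  # sensor noise
result = unmix_nnls(np.clip(y, 0, None), basis)
for name, est, true in zip(FLUOROPHORES, result.values, c_true):
    print(f"{name:>10s}: estimated {est:.3f}  (true {true:.1f})")
print(f"residual norm: {result.residual_norm:.3f}")
```

```
   PpIX634: estimated 2.004  (true 2.0)
   PpIX620: estimated 0.798  (true 0.8)
      NADH: estimated 0.502  (true 0.5)
lipofuscin: estimated 0.299  (true 0.3)
   flavins: estimated 0.401  (true 0.4)
residual norm: 0.173
```

The abundances come back within the noise level, and the PpIX634 estimate —
the channel surgeons care about — is accurate to 0.2%.

Run a complete seeded pipeline (simulate a small margin cohort, render and
preprocess a cube, unmix, run the statistics, train and evaluate a
classifier, render a report):

```bash
hsfluor demo --seed 0 --out demo_run
```

This writes `demo_run/manifest.json` (all artifacts with SHA-256 checksums),
`demo_run/evaluation_report.json` and `demo_run/report/report.md` with
confusion-matrix, ROC, PCA-scatter and PpIX-overlay figures. With seed 0 the
demo's held-out test report is:

```
accuracy 0.883, macro one-vs-rest AUC 0.975
model: random_forest(criterion=gini, max_features=sqrt, min_samples_split=2, n_estimators=100)
confusion matrix (rows = true IZ, RABT, ST):
 [[51, 7, 2], [8, 52, 0], [4, 0, 56]]
```

i.e. on this small synthetic cohort the infiltrating zone (IZ) is the class
most often confused with solid tumor (ST) and reactive tissue (RABT), while
ST and RABT are rarely confused with each other — the error structure one
expects from a margin gradient. Re-running with the same seed reproduces the
same checksums bit for bit.

The numbered scripts under `analysis/` run the same stages at cohort scale
(published per-class biopsy rosters) and write their tables under
`results/`: dataset composition, cube-level unmixing fidelity, PCA
variance-explained per task, the KS significance battery, and the four
classification tasks.

## Documentation

`docs/methods.md` describes the signal model, the synthetic cohort generator
and what it does and does not emulate, numerical choices, and known
limitations.
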