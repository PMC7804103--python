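# resectquant

Quantification of residual enhancing tumor on early post-operative brain MRI,
exercised end-to-end on synthetic phantoms and synthetic cohorts with known
ground truth. The package covers:

- **synthetic phantoms** (`resectquant.phantom`) — resection-cavity T1w/T1wC
  pairs with an enhancing rim of controllable thickness, DSC bolus curves with
  controllable leakage, and survival cohorts whose hazard is log-linear in rim
  thickness; every generator carries its exact ground truth.
- **preprocessing** (`resectquant.preprocess`) — multiplicative bias-field
  correction, landmark (decile) histogram standardization, resampling, rigid
  mutual-information registration, cross-sequence gain/offset intensity
  matching, and the T1wC − T1w subtraction enhancement map.
- **enhancement quantification** (`resectquant.enhancement`) — threshold +
  morphology segmentation and mean/max thickness from an anisotropic-spacing
  exact Euclidean distance transform (note: for a closed shell the transform
  maximum is the *half*-width of the shell; the statistic is still strictly
  monotone in true rim thickness).
- **DSC perfusion** (`resectquant.perfusion`) — Gaussian-dip curve selection,
  ΔR2\* conversion, linear leakage correction against a non-enhancing
  reference curve, white-matter-normalized rCBV with the 99th-percentile
  hot-spot statistic, and percentage of signal recovery.
- **radiomics** (`resectquant.radiomics`) — a 94-feature vector (first-order
  19, GLCM 24, GLRLM 16, GLSZM 16, NGTDM 5, GLDM 14) after 1 mm isotropic
  resampling and fixed-bin-width discretization, plus a coefficient-of-
  variation robustness screen (robust iff CoV < 20%).
- **survival modelling** (`resectquant.survival`) — Cox (Efron ties) and
  Kaplan–Meier/log-rank analyses overall and per scan-delay window
  (< 24 / 24–48 / 48–72 / ≥ 72 h) with Benjamini–Hochberg adjustment,
  2-year dichotomized logistic/ROC models with DeLong CIs and Youden
  thresholds, stratified 70/30 splitting, training-set z-scoring, mRMR and
  AIC-stepwise feature selection, and the nested combined prognostic models.
- **pipeline + CLI** (`resectquant.pipeline`, `resectquant.cli`) —
  per-patient orchestration with crash isolation, provenance (version +
  config hash) in every output, and a Table-1-shaped markdown report.

## Tests

```bash
python -m pytest -q tests/
```

The suite contains per-module unit tests, property tests (exact
distance-transform equivalence with an exhaustive brute-force oracle,
AUC = concordant-pair fraction, BH step-up formula, radiomics texture
matrices vs loop-based reference code), and `tests/test_acceptance.py` with
one test per acceptance criterion.

## CLI

```bash
resectquant simulate   --spec spec.yaml --out DIR      # synthetic data + truth
resectquant preprocess --t1w a.nii.gz --t1wc b.nii.gz --out DIR
resectquant thickness  --mask m.nii.gz                  # JSON {mean_mm, max_mm, volume_ml}
resectquant perfusion  --dsc d.nii.gz --mask m.nii.gz --wm wm.nii.gz
resectquant radiomics  --image i.nii.gz --mask m.nii.gz [--robustness]
resectquant analyze    --cohort cohort.csv --out report/
resectquant run        --config pipeline.yaml --out DIR # full cohort pipeline
```

`simulate` reads a YAML with optional `phantom`, `dsc` and `cohort` blocks
(field names mirror `PhantomSpec`, `DscCurveSpec`, `CohortSpec`). `run` reads
a pipeline config with a `patients:` manifest mapping patient ids to
`t1w`/`t1wc`/`dsc`/`wm` paths. Exit codes: 0 success, 2 partial (some
patients failed), 1 fatal.

## Conventions

- Volumes are `(i, j, k)`-indexed arrays with per-axis spacing in mm; voxel
  centers sit at `origin + index * spacing`. NIfTI-1 I/O via nibabel.
- Distance transform: distance from each foreground voxel center to the
  nearest in-array background voxel center.
- Percentiles use the linear-interpolation convention (rCBV-99 depends on it).
- Discretization for radiomics is anchored at the mask minimum:
  `level = floor((v - min) / bin_width) + 1`.
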