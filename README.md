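# boldcv

Fluctuation-amplitude analysis of resting-state BOLD fMRI, built around the
per-voxel **coefficient of variation**

```
CV_i = sd_t( S_i(t) ) / mean_t( S_i(t) )
```

— the temporal standard deviation of a voxel's signal divided by its
temporal mean.  The CV of spontaneous BOLD fluctuations is a candidate
marker of cerebrovascular reactivity: it is elevated in elderly
hypertensive patients with chronic kidney disease relative to young
healthy adults, in gray and white matter alike, and the elevation is
carried mainly by very low frequencies (f < 0.025 Hz).

The package is aimed at researchers who want to compute and compare tissue
CV values between cohorts, and at methods developers who need a fully
seeded synthetic testbed for such pipelines.  It provides:

* **Preprocessing** — per-voxel OLS regression of the 6 rigid-body motion
  parameter time-courses, first-order polynomial detrending, and
  RETROICOR: slice-specific cos/sin regressors in cardiac and respiratory
  phase (order 2, 8 columns), with cardiac phase from detected
  photoplethysmograph peaks and respiratory phase from histogram
  equalisation of the belt amplitude.  Every step preserves the voxel's
  temporal mean and never increases its variance.
* **CV mapping** — full-band CV maps and band-limited CV via a zero-phase
  DFT-mask filter (default bands 0.01–0.014, 0.014–0.025, 0.025–0.1 Hz),
  with an exact Parseval variance partition across disjoint bands.
* **Tissue aggregation** — three segmentation strategies: the
  partial-volume-weighted mean `sum(PVE_i * CV_i) / sum(PVE_i)`, the
  strict-threshold mean over voxels with PVE > 0.8, and the plain mean
  over a supplied binary template mask or drawn ROI.
* **Cohort statistics** — the exact two-sided Wilcoxon rank-sum test
  (dynamic-programming null for untied data, full enumeration with ties,
  tie-corrected normal approximation for large samples), an OLS fit of the
  WM-vs-GM relation, and per-stratum group summaries.
* **A synthetic BOLD phantom** — concentric-ellipsoid head geometry with
  fractional GM/WM/CSF maps, band-limited power-law intrinsic fluctuations
  calibrated to target tissue CVs, linear scanner drift, jittered
  pulse-train cardiac and quasi-sinusoidal respiratory components sampled
  at interleaved slice times, thermal noise, and optional rigid motion
  drift — all reproducible from one seed, with ground truth retained.

## Worked example

Generate and analyse a small two-cohort phantom study (3 subjects per
group on a 24³ grid, TR 2 s, 180 volumes; the control group carries
intrinsic GM/WM CVs of 4.6/3.0 ×10⁻³, the CKD-analog group 7.9/4.2 ×10⁻³):

```sh
cat > study.yaml <<'YAML'
n_per_group: 3
control:
  grid_shape: [24, 24, 24]
  motion_amp_mm: 0.2
ckd:
  grid_shape: [24, 24, 24]
  motion_amp_mm: 0.2
  tissue_cv: {GM: 7.9e-3, WM: 4.2e-3, CSF: 15.0e-3}
YAML
boldcv phantom-study --config study.yaml --out out --seed 1
```

prints (abridged):

```
Cohort comparison of BOLD fluctuation CV
============================================
  GM   strict   0.01-0.014Hz: control 3.33±0.01 vs ckd 5.76±0.02 (CV x1e-3), p=0.1
  GM   strict           full: control 4.49±0.01 vs ckd 7.66±0.01 (CV x1e-3), p=0.1
  WM   strict           full: control 3.13±0.02 vs ckd 4.44±0.01 (CV x1e-3), p=0.1
WM vs GM fit: y = 0.414 x + 0.0013, R^2 = 1 (n=6)
mean displacement (mm): control 0.0674, ckd 0.07; p = 0.1
```

Reading the output: each row is one tissue × aggregation-method ×
frequency-band stratum with the group means ± SD of the per-subject CVs
(×10⁻³) and the exact rank-sum p-value.  The full pipeline (RETROICOR,
motion regression, detrending) recovers the generated CV levels to within
a few percent; the lowest band carries the largest share of the CV; and
with 3 subjects per group the smallest attainable exact p is
2/C(6,3) = 0.1, which is what every stratum reaches here.  The same
analysis is available programmatically via
`boldcv.run_phantom_study(...)`, and real data can be processed with
`boldcv run --config cohort.yaml` or `boldcv subject --bold ... --gm-pve
... --wm-pve ...` given NIfTI images, motion-parameter text files and
physio TSVs (see `boldcv <command> --help`).

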