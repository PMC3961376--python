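# Methods

## The measurement

For a voxel time series `S_i(t)`, `t = 1..T`, the fluctuation amplitude is
the coefficient of variation `CV_i = sd(S_i)/|mean(S_i)|`, using the
sample (n−1) standard deviation throughout (the convention is stated so
results are reproducible bit for bit; at T = 180 the n−1 factor inflates
the CV by 0.28% relative to the population convention).  Voxels whose
temporal mean is within 1e-6 of zero relative to the in-mask median mean
are flagged invalid and receive zero weight everywhere downstream — the
floor is relative so results are independent of signal units, which also
makes the CV exactly scale invariant.

Nuisance removal precedes CV mapping in the order: RETROICOR (when physio
recordings exist) → motion-parameter regression → first-order detrending.
Each step fits mean-centered regressors plus an intercept by per-voxel
OLS and subtracts only the regressor component, so the temporal mean — the
CV denominator — is preserved exactly and the numerator can only shrink
(orthogonal projection: variance non-increasing, idempotent).  Motion
regression uses the six rigid-body parameter time-courses as-is, without
derivatives or squares; a rank-deficient design is handled through the
pseudoinverse with a warning.  All-zero motion parameters mean "no
recorded motion" and the stage is skipped rather than constructing a
degenerate design.

## RETROICOR

Cardiac phase is piecewise linear between pulse peaks: `φc(t) = 2π(t −
t_k)/(t_{k+1} − t_k)`; times outside the detected range extrapolate with
the nearest interval's rate.  Peaks are detected on a lightly smoothed
trace (0.1 s moving average — about a tenth of a cardiac period, symmetric
so peak positions are unbiased) with an adaptive threshold `rolling_median
+ 0.5 × rolling_range` over 2 s windows, a 0.25 s refractory period
(240 bpm ceiling), and parabolic sub-sample refinement.  Respiratory phase
uses amplitude histogram equalisation (100 bins over the run) signed by
the derivative of the 1 s-smoothed belt trace, mapping inspiration and
expiration to opposite half-cycles.  The Fourier model order is 2, giving
8 slice-specific regressors (cos/sin of 1×, 2× each phase), evaluated at
each slice's acquisition offset within the TR.

On phantoms with a known injected physiological component these
regressors remove ≥ 99% of the physiological variance in high-amplitude
voxels.  With zero injected physiology they change the mean per-voxel CV
by < 1% (the 8-dof projection of a 180-sample series removes little, and
less than the naive 8/179 expectation because the regressors are
narrowband at the aliased cardiac/respiratory frequencies, largely
outside the 0.01–0.1 Hz fluctuation band); individual voxels in the tail
of that projection can move by ~2%.

## Band decomposition

Band-limited CV applies a zero-phase ideal (DFT-mask) filter to the
mean-removed series.  Bin selection is half-open, `low < f ≤ high`, and
never includes DC; adjacent bands therefore partition the frequency axis
exactly and the band variances sum to the total variance to ~1e-15
relative (Parseval).  No padding or tapering is applied; for short series
the rectangular-window leakage is accepted as a documented limitation.
Filtering happens after all confound removal.  The default bands are
0.01–0.014, 0.014–0.025 and 0.025–0.1 Hz; at TR = 2 s and T = 180 the
spectral resolution is 1/360 Hz, so the narrowest band contains two bins.

## Aggregation

The PVE-weighted mean is `sum(PVE_i·CV_i)/sum(PVE_i)` over valid brain
voxels; the strict-threshold mean averages voxels with `PVE > 0.8`
(strictly — a voxel at exactly 0.8 is excluded); the template mean
averages a supplied pre-aligned binary mask, and the same operation
serves manually drawn ROIs.  A strict-threshold mask with fewer than 2000
voxels triggers a warning, since tissue means are assumed to average over
a large voxel population.  No resampling or registration is performed;
all images must share one grid.

## Cohort inference

The two-sided Wilcoxon rank-sum p is `2·min(P(S ≤ s), P(S ≥ s))` capped
at 1, where `S` is the first sample's rank-sum (midranks under ties).
For untied samples with both n ≤ 12 the null distribution is built by a
subset-sum dynamic program over ranks, O(n1·n2·N); with ties and pooled
N ≤ 20 all C(N, n1) midrank subsets are enumerated; otherwise the normal
approximation with tie-corrected variance and a 0.5 continuity correction
is used.  Equality with brute-force enumeration is property-tested for
all small sample sizes, and the exact and approximate p agree within 0.01
at n = 10 per group.  If every pooled value is identical the test is
degenerate and returns p = 1 with a warning.  No multiple-testing
correction is applied across tissue/method/band strata; p-values are
reported unadjusted with a 0.05 significance threshold.

The WM-vs-GM relation is an ordinary least-squares line fitted with WM on
the y-axis and GM on the x-axis (one point per subject, strict-threshold
full-band values), reported as slope, intercept and R².

## The phantom

The phantom is a signal-level simulator: no k-space, relaxation or EPI
distortion physics.  Geometry is three concentric ellipsoids (GM shell,
WM core, central ventricular CSF) with semi-axes 0.45/0.28/0.10 of the
grid half-extent; hard labels are smoothed with a 0.6-voxel Gaussian and
renormalised so tissue fractions sum to exactly 1 inside the brain
envelope.  On the default 32³ test grid this yields ~8000 GM voxels above
the 0.8 purity threshold.  Baseline intensities are 1000/950/750 (a.u.)
for GM/WM/CSF.

Per voxel, the generated signal is

```
S_i(t) = S0_i · (1 + cv_i·u_i(t) + d·t/T_scan + a_i·p(t_slice)) + ε_i(t)
```

* `u_i` — intrinsic fluctuation: random-phase Fourier synthesis with
  deterministic bin amplitudes `f^(β/2)` confined to 0.01–0.1 Hz,
  rescaled to unit sample standard deviation.  Spectral confinement and
  variance calibration are therefore exact by construction, so any
  downstream CV error reflects the pipeline, not synthesis sampling
  noise.  The default exponent is β = −3: the band variance of a power
  law is `∫ f^β df`, and β must be steeper than about −2 for the
  0.01–0.014 Hz band to dominate the 0.025–0.1 Hz band as observed in
  this kind of data ("fast initial decay" of the low-frequency spectrum);
  β = −1 would make the widest band dominate.  The exponent is a config
  field, flagged as the one deliberately assumed quantity the emulated
  measurement does not constrain beyond the band ordering.
* drift — linear, default 1% of baseline over the run.
* physio — a von-Mises-shaped pulse train (κ = 2, so almost all pulse
  power sits in the first two cardiac harmonics, consistent with the
  quasi-periodicity RETROICOR assumes) at 1.13 Hz with 5% RR jitter, plus
  an amplitude-modulated 0.3 Hz respiratory sinusoid; both sampled at each
  voxel's slice acquisition time (even-spaced offsets, interleaved order,
  even slices first) and scaled by a PVE-mixed tissue amplitude — largest
  in CSF (0.4% of baseline), smallest in WM (0.1%), reflecting the high
  fluctuation amplitudes at CSF boundaries.
* thermal — white Gaussian noise, default 0.05% of baseline, small enough
  to contribute < 5% of the fluctuation variance for every tissue so that
  parameter-recovery experiments are not noise-limited.

True cardiac peak times, the per-voxel intrinsic CV and the tissue
fraction maps are retained as ground truth.  Motion parameters default to
zero; `motion_amp_mm > 0` injects a smooth rigid drift plus small tremor
(keeping the six columns independent) so the regression stage can be
exercised — the BOLD data itself is not moved, since realignment is out
of scope and the parameters act only as regressors.

What the phantom does **not** emulate: spatial autocorrelation of the
fluctuation field (voxels are independent), vascular/vessel structure,
non-rigid pulsatile brain motion, susceptibility artifacts, and any
nonstationarity beyond slow respiratory amplitude modulation.  Passing
recovery tests therefore demonstrates correctness of the estimator chain
under the stated signal model, not robustness to every property of real
acquisitions.

## Study conditions and problem sizes

The recovery experiments use 10 subjects per cohort on a 32³ grid with
TR 2 s and 180 volumes — a desk-scale stand-in for the emulated protocol
(64×64×35 voxels), chosen so the whole two-cohort study runs in tens of
seconds.  Control-analog subjects carry intrinsic GM/WM CVs of
4.6/3.0 ×10⁻³ and CKD-analog subjects 7.9/4.2 ×10⁻³ (strict-threshold
group means); CSF is set to roughly twice GM in each cohort, as ventricle
fluctuation amplitudes are not reported at the group level.  Recovered
cohort means sit ~2–3% below the generated levels: the 14 nuisance
regressors (8 RETROICOR + 6 motion) absorb a small fraction of genuine
fluctuation variance, partly offset by the thermal-noise contribution.
Both effects are well inside the between-subject SDs used as recovery
tolerances.

## Numerical conventions and edge cases

* Sample (n−1) standard deviations everywhere, including band CVs.
* The CV denominator is the preserved temporal mean, identical before and
  after detrending by construction.
* Phase extrapolation outside the detected peak range uses the nearest
  interval; respiratory phase at a derivative zero-crossing takes sign 0
  (phase 0) at that instant.
* Rank-deficient nuisance designs: pseudoinverse with a warning, which is
  equivalent to pruning dependent columns.
* Degenerate inputs fail loudly: empty masks, constant respiratory
  traces, < 3 detected cardiac peaks, non-4D images, non-finite voxels,
  negative PVE, short physio coverage.
* Rotation-to-displacement conversion uses a 50 mm head radius in the
  framewise-displacement summary.
* All randomness flows from a single integer seed per subject; identical
  specs produce bit-identical subjects, and the pipeline itself is fully
  deterministic.
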