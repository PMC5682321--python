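# Methods

This note documents the models implemented in `stgc`, the conventions chosen
where several were defensible, and what the synthetic validation studies do
and do not establish.

## Windowed Granger causality

### Estimator

For an ordered pair of series the causality from `x` to `y` at order `p` is
the in-sample log residual-variance ratio `ln(s2_restricted / s2_full)`
(Geweke convention). Both models are ordinary least squares on the same
effective sample (rows `p .. T-1`): the restricted design holds `p` lags of
`y` plus an intercept, the full design adds `p` lags of `x`. Because the
models are nested and fit in sample, the estimator is non-negative; its null
mean decays like the number of extra regressors over the effective sample
size (~`p/n`), which the permutation machinery — not an analytic correction —
accounts for in inference.

Conventions, each chosen once:

* **Centering.** Series are de-meaned per fitted segment *and* the designs
  carry an explicit intercept. The intercept makes noise-free deterministic
  recursions (e.g. `x_t = 0.9 x_{t-1}`) recover their coefficients exactly,
  which pure pre-demeaning does not.
* **Residual-variance denominator.** Maximum-likelihood (`RSS / n_effective`,
  with `n_effective = window_length − p`), used consistently in the GC ratio,
  `GC_err`, and BIC.
* **Model order.** Selected per window by BIC of the unrestricted target
  equation, with all candidate orders scored on the common sample starting at
  `max(order_range)` so their likelihoods are comparable. Default range 1–5.
  Parameter count is `2p + 1` (both lag blocks plus the mean). The bivariate
  VAR determinant criterion was considered and rejected as costlier without
  changing selections materially.
* **Degenerate inputs.** Constant series raise; an exactly predictable target
  (zero full-model residual variance) yields `+inf` flagged by a warning; a
  window-level degenerate can be excluded from the averages by
  `on_degenerate="exclude"`, otherwise the failure is loud.

### Windowing

`prepare_series` drops a fixed number of leading volumes (start-up
transients; default 2) and retains the last `keep_last` (default 208) of the
remainder, split into `n_windows` (default 4) contiguous equal windows — the
resting-state protocol of a 210-volume, TR = 2 s acquisition. `keep_last`
must divide evenly; a violation is a configuration error raised before any
computation.

`GC_avg` is the plain mean of per-window GC values; `GC_err` is the mean of
per-window full-model residual variances weighted by effective sample size
(the weights matter only when window lengths or selected orders differ). The
windowed objective is `J = GC_err + 1/GC_avg`, with `J = +inf` when `GC_avg`
falls below machine epsilon (logged).

### Window-length selection

Candidates that do not divide the retained length are truncated from the
start to their largest multiple. Selection minimises `J`, but a pure argmin
is structurally biased toward the shortest candidate: in-sample residual
variance *and* in-sample GC both inflate as windows shrink, so the shortest
admissible window essentially always attains the smallest `J`, regardless of
the true regime structure. The implemented rule therefore treats candidates
whose `J` intervals (± one delta-method standard error, computed from the
per-window dispersion of GC and residual variance) overlap the minimiser's
interval as statistically tied, and resolves ties by the lowest **total
windowed BIC** `Σ_w [n_w ln s2_w + (2 p_w + 1) ln n_w]`, preferring fewer,
better-estimated windows; any remaining tie goes to the longer window. BIC
grows with the number of windows through its parameter penalty, so
over-segmentation is penalised exactly where `J` cannot see it, while a
candidate window that straddles a regime change loses on both `J` (diluted
`GC_avg`, inflated `GC_err`) and the BIC fit term. In the alternating-regime
recovery study (52-point regimes, coupling 0.9, candidates {26, 52, 104})
this rule recovers the planted length in 85–90 % of replicates; argmin-`J`
recovers it in under 5 %.

### Spatial level and inference

ROI-level GC is the unweighted mean of windowed `GC_avg` over all ordered
(source voxel, target voxel) pairs; the edge matrix evaluates every ordered
ROI pair with a zero diagonal. Significance uses a permutation null: the
source series is fully time-permuted (destroying lagged dependence and
serial structure of the source alike), which is exact for exchangeable
sources and the convention adopted here. Under white-noise inputs the
empirical rejection rate at the null 95th percentile is 5 % within binomial
error (1000 replicates); planted lag-1 coupling of 0.4 at 208 points is
detected in ≥ 90 % of replicates with the reverse direction at the null rate.

## Diffusion metrics

Tensors are fit per voxel by log-linear least squares of
`ln S = -b g'Dg + ln S0` (62 unknowns-to-measurements ratio 7:65 with the
default scheme of 61 isotropic b = 3000 s/mm² directions + 4 b = 0).
Eigenvalues are sorted descending and negative values clamped to zero with
the clamp count recorded. Scalars follow the standard closed forms; FA is
clipped into [0, 1] against rounding.

**Rician noise floor.** At b = 3000 the along-fibre signal of healthy white
matter (`e^{-5.1} ≈ 0.006`) lies far below the noise floor at SNR 30
(σ ≈ 0.033), which biases the raw fit severely enough to *invert* planted
axial-diffusivity group differences. `fit_tensor` therefore accepts a
`rician_sigma` and applies the standard second-moment correction
`sqrt(M² − 2σ²)` (clipped at 0.2 σ) before the log fit; the pipeline
estimates σ by pooling the b = 0 repeats across voxels. Signal-weighted and
censored fits were evaluated and performed worse on this failure mode.

**Free water.** With a single non-zero shell the pair (f, tissue
diffusivity) is not identifiable, so the tissue diffusivity is fixed per run
(default 0.7×10⁻³ mm²/s) and the bi-exponential shell-average model is
linear in `f`; the bounded solution is the projected closed form. Passing
`tissue_d=None` with ≥ 2 shells co-estimates both by bounded least squares.
With `rician_sigma` given, shell attenuations use floor-corrected second
moments (RMS), since the free-water signal at b = 3000 is itself sub-floor.
Voxels with `f` above the masking threshold (default 0.7, chosen as a
conservative CSF cut) are excluded from tract averages; tract means are
unweighted over unique unmasked voxels (no visitation weighting).

## Group and association statistics

The two-sample t-test is the pooled-variance (Student) form — the printed
`df = n1 + n2 − 2 = 44` of the motivating cohort forces this choice — and the
summary-statistics and raw-data paths agree exactly on moment-matched data.
Zero pooled variance yields p = 1 for equal means and a degenerate flag
otherwise. Fisher's exact test is two-sided by probability summation; a zero
margin yields p = 1. Of note, the standard convention gives p ≈ 0.77 for a
15M/11F vs 10M/10F gender split, not the 1.00 sometimes reported for such
tables. Bonferroni thresholds are `alpha/m` with `m` configurable (the
pipeline defaults to the number of tests actually run; `m = 36` reproduces a
0.0014-level threshold at alpha 0.05). FDR control is Benjamini–Hochberg
step-up. Associations are OLS of the subject metric on memory score plus
intercept, gender, age and mean framewise displacement; incomplete cases are
dropped listwise with a logged count, and rank-deficient designs fail naming
the dependent columns.

## Synthetic cohort generator

The generator's defaults (`stgc/defaults.yaml`, versioned with the package)
encode the emulated study: 26 controls vs 20 patients; 10 ROIs (mPFC, PCC,
bilateral MTG, IPL, hippocampus, thalamus) with 5 voxels each; 210 timepoints
at TR = 2 s; 61-direction b = 3000 single-shell DWI with 4 b = 0 volumes at
SNR 30 (Rician).

* **BOLD.** One latent process per ROI follows a (piecewise) VAR(1) with
  spectral-radius-validated coupling matrices; voxels share the latent at a
  within-ROI correlation of 0.7 (`sqrt(rho)·latent + sqrt(1−rho)·noise`,
  equal variances), mirroring the spatial coherence an ICA-derived component
  implies. Healthy directed couplings default to 0.4 (thalamus→IPL) and 0.35
  (cortico-cortical); the patient group attenuates the planted
  thalamus→IPL edge to 0.4 of its healthy value. An optional canonical
  double-gamma HRF convolution is available; it is off in the validation
  studies because it lowpasses lag-1 structure without changing the
  qualitative contrasts.
* **DWI.** Tract voxels draw eigenvalues around (1.7, 0.3, 0.3)×10⁻³ mm²/s
  with ~3 % subject-level and ~5 % voxel-level lognormal jitter and uniform
  random orientation; patient tracts are perturbed by (ΔAD, ΔRD) pairs
  (defaults up to +0.25/+0.15 ×10⁻³ on the thalamo-parietal tract), giving
  FA drops of 0.07–0.09 with raised MD/RD/AD — the full direction pattern of
  interest. Tract borders carry planted free-water voxels (f = 0.9).
  Effect sizes were fixed once, at design time, such that the measured
  (noise-floor-corrected) group contrasts reach the Bonferroni-corrected
  desk-scale power the validation suite demands; the measured axial contrast
  is strongly compressed by the b = 3000 protocol, so the planted ΔAD is
  deliberately larger than the FA-matched minimum.
* **Covariates.** Demographics and neuropsychological scores are drawn from
  the cohort's printed moments (fixed gender counts 15M/11F and 10M/10F);
  motion is lognormal mean framewise displacement. The memory score couples
  to the planted tract's per-subject FA only in the patient group
  (generating correlation −0.75, sign following the reported direction),
  with controls at exactly zero.

Everything is reproducible bit-for-bit from `(spec, seed)`; the pipeline
derives independent child seeds per stage and subject from the run seed, so
the GC and DTI halves can be rerun in isolation with identical results.

### What the generator does not emulate

No brain geometry, registration, physiological noise, scanner drift, or
hemodynamic variability across regions; free water appears only at planted
border voxels; tractography itself is out of scope (tracts are consumed as
voxel coordinate sets). Passing validation therefore demonstrates that the
estimators recover the effects they are pointed at under the stated noise
model — not that the pipeline is robust to the full failure modes of real
acquisitions (HRF latency confounds of lag-based causality in particular are
a known, documented limitation of GC on BOLD).

## Problem sizes in the validation studies

Null calibration uses 1000 white-noise replicates against a pooled
2000-permutation null; power uses 100 replicates with 10 permutations each;
window recovery uses 100 replicates; the end-to-end dissociation study
replicates the full 46-subject cohort 50 times, computing the planted
thalamo-parietal edge (25 voxel pairs per subject) and all three planted
tracts per subject. These sizes give binomial standard errors of ~0.7–4
percentage points on the reported rates.
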