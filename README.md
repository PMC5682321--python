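# stgc — spatio-temporal Granger causality and thalamo-cortical tract metrics

`stgc` is a Python library for joint *effective*- and *structural*-connectivity
analysis of resting-state fMRI and diffusion MRI, built around the kind of
two-group study that compares healthy older adults with amnestic mild
cognitive impairment (aMCI) patients on (i) directed interactions between the
thalamus and default-mode-network (DMN) nodes and (ii) the microstructural
integrity of the white-matter tracts connecting them, and relates both to
memory performance.

Because clinical MRI datasets of this kind are rarely shareable, the package
ships a first-class synthetic cohort generator that emulates the study design
end to end — multivoxel BOLD series from vector-autoregressive networks,
single-shell diffusion signals over synthetic tracts with planted group
differences and free-water contamination, and a covariate table with a
group-specific structure–memory coupling — so every statistical claim the
pipeline makes can be validated against known ground truth.

## The methods

**Windowed Granger causality (GC).** For series \(x \to y\) and model order
\(p\), GC is the Geweke log variance ratio

\[ \mathrm{GC}_{x\to y} = \ln\frac{\hat\sigma^2_{\text{restricted}}}{\hat\sigma^2_{\text{full}}} , \]

where the restricted model regresses \(y_t\) on its own \(p\) lags and the
full model adds \(p\) lags of \(x\); both are fit in sample on the same
effective sample, so GC ≥ 0. To respect time-varying coupling, the series is
split into \(m\) equal windows (the resting protocol retains the last 208 of
210 volumes after dropping 2 start-up transients → 4 windows of 52 at
TR = 2 s); each window is refit with a BIC-selected order. A candidate window
length is summarised by the average causality \(\mathrm{GC}_{avg}\), the
sample-size-weighted residual variance \(\mathrm{GC}_{err}\), and the
objective

\[ J = \mathrm{GC}_{err} + 1/\mathrm{GC}_{avg}, \]

minimised over candidate lengths; statistically tied candidates (within one
standard error of the minimiser) are resolved by total windowed BIC. ROI-level
GC is the mean windowed GC over all ordered voxel pairs of the two ROIs.
Significance is assessed against a permutation null (source series permuted in
time).

**Tract diffusion metrics.** Voxelwise diffusion tensors are fit by log-linear
least squares of \(\ln(S/S_0) = -b\,g^{\mathsf T} D g\); eigenvalues
\(\lambda_1\ge\lambda_2\ge\lambda_3\) give MD \((\lambda_1+\lambda_2+\lambda_3)/3\),
AD \(\lambda_1\), RD \((\lambda_2+\lambda_3)/2\) and
FA \(=\sqrt{3/2}\,\lVert\lambda-\mathrm{MD}\rVert/\lVert\lambda\rVert\).
At b = 3000 s/mm² the Rician noise floor dominates strongly attenuated
signals; an optional second-moment correction \(\sqrt{M^2-2\sigma^2}\) (σ from
the b = 0 repeats) de-biases the fit. Free-water voxels are identified by a
single-parameter bi-exponential signal-fraction fit
\(S(b)/S_0=(1-f)e^{-b d_t}+f e^{-b d_w}\) with \(d_w = 3.0\times10^{-3}\)
mm²/s and masked at \(f > 0.7\) before unweighted tract averaging.

**Group and brain–behaviour statistics.** Pooled-variance two-sample t-tests
(raw data or printed mean/SD/n), Fisher's exact test, Bonferroni (\(\alpha/m\))
and Benjamini–Hochberg FDR control, and OLS association of per-subject metrics
with memory adjusted for gender, age and motion.

## Worked example

`examples/` contains one narrative script per capability. Windowed GC with
window-length selection (`examples/01_windowed_granger.py`) on a series whose
coupling alternates in 52-point regimes prints:

```
classic (unwindowed) GC x->y : 0.1655
per-window GC                : [0.0037, 0.4592, 0.0547, 0.5011]
GC_avg=0.2547  GC_err=0.8782  J=4.805
  window  26: J=  3.867  BIC=    26.53
  window  52: J=  4.805  BIC=    19.67
  window 104: J=  7.045  BIC=    26.36
selected window length       : 52
```

The per-window GC values follow the planted off/on/off/on coupling pattern —
structure a single whole-series fit dilutes (0.17) — and the selection
recovers the true 52-point regime length. The end-to-end study
(`examples/04_full_pipeline.py`, a reduced 12 + 12 cohort) prints the planted
dissociation: lower patient FA with raised MD/RD/AD on thalamo-cortical
tracts and reduced thalamus→IPL effective connectivity, all Bonferroni
significant, plus an FA–memory association present in patients
(t(7) = −3.83, p = 0.006) and absent in controls (p = 0.99).

The same pipeline is scriptable from the shell:

```bash
stgc simulate --out cohort/ --seed 1        # synthetic cohort on disk
stgc run --out run/ --seed 1                # simulate -> GC + DTI -> statistics
stgc dti --dwi dwi.nii.gz --bvals bvals --bvecs bvecs --tracts tracts.csv --out maps/
stgc report --run-dir run/
```

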