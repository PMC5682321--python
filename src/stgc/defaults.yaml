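# Versioned defaults for the synthetic cohort generator.
# Diffusivities are in mm^2/s, b-values in s/mm^2, times in seconds.

network:
  roi_names: [mPFC, PCC, L-MTG, R-MTG, L-IPL, R-IPL,
              L-Hippocampus, R-Hippocampus, L-Thalamus, R-Thalamus]
  voxels_per_roi: 5
  within_roi_correlation: 0.7
  noise_sd: 1.0
  self_coupling: 0.3
  n_timepoints: 210
  tr_seconds: 2.0
  # healthy-control directed lag-1 couplings (source -> target)
  couplings:
    "L-Thalamus->L-IPL": 0.4
    "L-MTG->L-IPL": 0.35
    "PCC->R-IPL": 0.35

cohort:
  n_hc: 26
  n_patient: 20
  # patient coupling = factor * healthy coupling
  edge_effects:
    "L-Thalamus->L-IPL": 0.4
  subject_coupling_sd: 0.05
  # per-group correlation between planted-tract FA and memory score
  memory_coupling:
    hc: 0.0
    amci: -0.75
  memory_mean:
    hc: 70.0
    amci: 55.0
  memory_sd: 10.0
  memory_tract: "L-Thalamus->L-IPL"

dwi:
  snr: 30.0
  n_directions: 61
  n_b0: 4
  bval: 3000.0
  tissue_eigenvalues: [0.0017, 0.0003, 0.0003]
  # patient eigenvalue perturbations per planted tract (delta_ad, delta_rd)
  tract_effects:
    "L-Thalamus->L-IPL": {delta_ad: 0.00025, delta_rd: 0.00015}
    "L-Thalamus->L-Hippocampus": {delta_ad: 0.0002, delta_rd: 0.0001}
    "L-Thalamus->PCC": {delta_ad: 0.0002, delta_rd: 0.0001}
  subject_eigen_sd: 0.03     # lognormal sd of per-subject eigenvalue factors
  voxel_eigen_sd: 0.05       # lognormal sd of per-voxel eigenvalue factors
  free_water_f: 0.9          # planted fraction on tract-border voxels
  free_water_threshold: 0.7  # masking threshold on estimated f
  tract_length: 30           # voxels along each synthetic tract core
  border_every: 5            # every n-th core voxel gets a free-water neighbour

validation:
  regime_coupling: 0.9   # lag-1 coupling in the alternating-regime recovery study

covariates:
  # Cohort moments used to draw demographic / neuropsychological scores
  age: {hc: [69.30, 6.35], amci: [69.05, 7.55]}
  education: {hc: [13.38, 3.73], amci: [14.32, 3.02]}
  mmse: {hc: [28.65, 0.85], amci: [27.05, 2.17]}
  gds: {hc: [0.77, 1.07], amci: [2.58, 2.27]}
  epq_e: {hc: [8.04, 2.47], amci: [5.53, 3.37]}
  epq_n: {hc: [2.69, 2.43], amci: [3.78, 3.39]}
  cr: {hc: [16.65, 3.62], amci: [16.58, 4.97]}
  male_count: {hc: 15, amci: 10}
  motion_log_mean: -1.9      # lognormal mean framewise displacement (mm)
  motion_log_sd: 0.4
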