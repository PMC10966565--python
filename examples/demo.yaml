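alpha: 0.05
cpm_groups:
- HC
- PKD
cpm_p_threshold: 0.3
duration: 20.0
effects:
- band: theta
  group: PKD
  kind: band_power
  magnitude: 2.0
  targets:
  - Frontal_Sup_Medial_L
  - Frontal_Sup_Medial_R
epoch_len: 2.0
fs: 500.0
lambda2: 0.1111111111111111
morlet_fc: 1.0
morlet_fwhm_tc: 3.0
n_per_group:
  HC: 6
  PKD: 6
n_perm: 200
n_regions: 10
norm_range:
- 2.0
- 90.0
paradigm: eyes_closed
pec_bands:
- high_gamma
pec_env_samples_per_point: 4
pec_subsample: 10
psd_overlap: 1.0
psd_window: 2.0
rejection_threshold_uv: 100.0
robustness_replicates: 25
run_cpm: true
seed: 0
simulate: true
subsample_fraction: 0.95
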