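# Study conditions for the synthetic reanalysis.
# Cohort mirrors a 400-region, seven-network resting-state study with
# 72 patients / 74 controls and 140 usable volumes per subject.
cohort:
  n_regions: 400
  n_networks: 7
  n_timepoints: 140
  n_patients: 72
  n_controls: 74
  # patients: compressed principal axis plus network shifts mirroring the
  # reported direction of group differences (patients higher on limbic,
  # frontoparietal and default-mode; lower on visual)
  gradient_compression: 0.8
  network_shift:
    visual: -0.15
    limbic: 0.20
    frontoparietal: 0.12
    default: 0.18
  noise_sd: 1.0
  n_genes: 500
  n_signal_genes: 40
  signal_beta: 2.0
  sa_length_scale: 30.0

gradients:
  density: 0.10
  n_components: 10

pls:
  n_components: 2
  n_perm: 1000
  n_boot: 1000

enrichment:
  n_sets: 50
  set_size: 50

paths:
  scratch: scratch/analysis
  results: results
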