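# Small demonstration vineyard: 2 cultivation treatments x 3 plots x 2 vines,
# scanned at the operational settings (0.5 deg steps, 50 Hz, 0.5 m/s).
# Roughly a minute end to end on one CPU.
seed: 20180125

scene:
  n_treatments: 2
  n_plots_per_treatment: 3
  n_vines_per_plot: 2
  treatment_labels: [S1, S2]

sensor: {}           # SICK-class defaults: 270 deg FOV, 0.5-20 m, 12 mm noise

trajectory:
  speed: 0.5         # m/s; with 50 Hz scans -> 10 mm slice spacing
  gnss_rate_hz: 10.0
  gnss_noise_sd: 0.02

filter:
  k_neighbors: 64
  nsigma: 1.0
  bud_height: 1.0    # m, the cross-section plane (training height)

alpha:
  candidates: [0.1, 0.3, 0.5, 0.7, 0.9]

stats:
  biomass_cv: 0.10   # simulated weighing/drying scatter on the ground truth
  make_plots: true
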