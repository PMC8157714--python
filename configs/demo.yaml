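# Demo pipeline configuration: desk-scale end-to-end run
# (synthesize -> fickian fit -> SE table -> hopping -> free volume).
seed: 42
stages: [synth, fickian, se, hop, fv]
outdir: pipeline_out
log_level: INFO
synth:
  truth_coefficients: [-15.0, 6.0, -2.0]
  rh_steps: [[70.0, 50.0], [50.0, 30.0], [30.0, 10.0]]
  noise_sd: 0.005
  n_points: 80
  n_shells: 60
  initial_radius: 4.0e-6
  jump: {k12: 1.0, k21: 4.0, dt: 1.0, n_steps: 40000}
  packing: {n_spheres: 300, radius: 0.15, box: [4.0, 4.0, 4.0]}
fickian:
  order: 2
  n_shells: 40
se:
  eta_coefficients: [9.0, -14.0, 2.0]
hop:
  lag_ps: 10.0
  candidates: [1, 2, 3]
  n_bootstrap: 10
fv:
  spacing: 0.05
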