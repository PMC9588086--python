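# Full synthetic demo: simulate every input and analyse it.
# Run with:  chipscreen run --config examples/demo_pipeline.yaml --outdir out/
seed: 1
stages: [transport, ladder, mixing, dilution, fcs, penetration, dose_response, cells]
transport:
  distance_um: 150.0
mixing:
  flow_rates_ul_min: [1.0, 1.5, 2.0, 5.0, 10.0]
  noise_sd: 1.0
dilution:
  fractions: [1.0, 0.51, 0.26, 0.0]
  noise_sd: 1.0
fcs:
  n_particles: 1.0
  tau_d_s: 2.35e-5
  p: 0.2
  triplet_amp: 0.15
  tau_t_s: 2.0e-6
  noise_frac: 0.02
  r0_m: 2.0e-7
penetration:
  c0_mm: 2.0
  diffusivity_m2_s: 2.55e-10
  depth_um: 250.0
  times_h: [1.0, 4.0, 24.0, 48.0]
  threshold_mm: 1.9
dose_response:
  top: 90.0
  bottom: 10.0
  ec50: 0.61
  hill: 2.0
  doses: [0.0, 0.25, 0.5, 1.0, 2.0, 4.0]
  noise_sd: 2.0
cells:
  n_live: 90
  n_dead: 10
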