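# Demo end-to-end run on simulated data.
# remikit run --config examples/run_config.yaml --out remikit_demo
seed: 1
n_rounds: 3
simulate: true
sim:
  image_shape: [256, 256]
  n_sites: 600
  n_domains: 40
  channel_affinities: [0.8, 0.8, 0.8]
  background_site_rate: 100
  label_prob: 0.8
  residual_fraction: 0.055
  round_gain: 1.15
  drift_per_round: [1.0, -0.5]
background_radius: 50
register_subpixel: false
minmax_rounds: [1, 2]
sweep_start: 0.01
sweep_stop: 0.95
sweep_step: 0.01
depth_bin_width: 1.0
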