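# Two-spheroid gel-seeded kill-on-contact co-culture scene.
# Run the full pipeline with:
#   spherotox run-all --config examples/demo_scene.yaml --out demo_out --seed 3
scene:
  domain_extent: [800.0, 500.0, 400.0]
  pixel_size: 2.0
  frame_interval: 1.0
  n_frames: 48
  spheroids:
    - {center: [230.0, 250.0, 140.0], radius: 110.0, n_cells: 150}
    - {center: [570.0, 250.0, 140.0], radius: 95.0, n_cells: 120}
  effector_density: 1875000.0   # 300 agents in this 1.6e-4 mL slab
  seeding_mode: gel
  speed: 30.0
  persistence_time: 0.5
  bias_strength: 0.5
  sensing_range: 100.0
  attachment_radius: 8.0
  infiltration_rate: 0.05
  kill_rate: 0.02
  uniform_kill_rate: 0.0
  fragment_decay: 24.0
  bleach_decay: 72.0
  noise_sd: 0.02
  rng_seed: 3
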