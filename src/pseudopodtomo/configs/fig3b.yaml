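# Polarity-recovery study: 28 pseudopodium scenes with the reported
# mixed barbed-end composition (74% tip-ward).
scene:
  volume_shape: [256, 256, 128]
  pixel_size: 1.1
  n_filaments: [15, 30]
  length_distribution: [60.0, 170.0]
  tip_fraction: 0.74
  tube:
    radius: 50.0
    length: 200.0
  support_z: 5.0
  receptor_count: 0
  noise_sigma: 0.4
  tilt_range: 60.0
n_scenes: 28
spacing: 8.0
box_edge: 32
slab_thickness: 11.0
k_classes_2d: 20
classify_iterations: 12
margin: 0.05
min_members: 10
alpha: 0.05
alpha_stringent: 0.01
n_min_votes: 5
seed: 20
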