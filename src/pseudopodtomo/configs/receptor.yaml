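# Receptor-recovery study: membrane tubes decorated with 12-nm bent
# receptors placed 50-70 nm above the support.
scene:
  volume_shape: [256, 256, 128]
  pixel_size: 1.1
  n_filaments: [8, 12]
  length_distribution: [60.0, 150.0]
  tip_fraction: 0.74
  tube:
    radius: 60.0
    length: 200.0
    clearance: 2.0
  support_z: 5.0
  receptor_count: 50
  receptor_height: 12.0
  receptor_band: [50.0, 70.0]
  noise_sigma: 0.4
  tilt_range: 60.0
n_scenes: 5
box_edge: 32
attach_band: [2.0, 12.0]
height_band: [50.0, 70.0]
tilt_max: 20.0
min_separation: 8.0
k_classes_3d: 2
classify_iterations: 10
measure_level: 0.5
seed: 101
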