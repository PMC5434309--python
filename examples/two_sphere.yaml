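# Bundled end-to-end example: virtual grinding of a bone sphere (r = 500 um)
# carrying a 50 um vessel channel, followed by registration, segmentation,
# reconstruction and morphometry.
workdir: out/two_sphere
seed: 0
simulate:
  preset: two_sphere_test
  n_runs: 34
  nominal_abrasion_um: 35.0
  tilt: [0.0, 0.0]
  abrasion_noise_sd_um: 2.0
  jitter_translation_sd_um: 10.0
  jitter_rotation_sd_deg: 0.5
  pixel_size_um: 5.0
voxel_um: 10.0
smoothing_iters: 10
diffusion_limit_um: 150.0
structures: [bone, vessel]
structure_name: sphere_phantom
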