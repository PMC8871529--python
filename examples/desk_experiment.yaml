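# Desk-scale study configuration: 40 mm phantom, half-dose level,
# all three processing arms. Reproduces the configuration used by the
# test suite and scripts/acceptance.py (see tomodose.study).
phantom:
  thickness_mm: 40.0
  voxel_mm: 0.2
  lateral_extent_mm: [27.2, 48.0]
  glandular_fraction: 0.5
  texture_correlation_mm: 3.0
thicknesses_mm: [40.0]
dose_labels: [reduce50]
arms: [without, msbf, pix2pix]
i0: 2000.0
electronic_sigma: 5.0
max_att: 4.0
n_train_pairs: 64
train:
  epochs: 100
  patch_px: 64
  gen_base_channels: 16
  gen_depth: 3
  alpha_l1: 50.0
  lr: 0.0002
master_seed: 1
out_dir: results/desk_run
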