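# Default pipeline configuration.  Every analysis constant is a named key so
# sensitivity analyses are one-line edits.
scene:
  frame_size_nm: [3000.0, 3000.0]
  n_clusters: 36
  channel_footprint_nm2: 900.0
  cluster_size_law: [geometric, 14.9]   # near-exponential channels-per-cluster
  min_edge_gap_law: [constant, 30.0]
  nucleus_radius_frac: 0.15
  group_effect: 0.79                    # disease-group multiplier on mean cluster size

emission:
  labeling_efficiency: 1.0
  blinks_per_fluorophore_law: [poisson, 20.0]
  localization_precision_nm: 12.0
  background_rate_per_um2: 0.5

render:
  sigma_render_nm: 16.0
  gain: 100.0

analysis:
  mask_fraction: 0.75                   # intensity fraction captured by the binary mask
  min_cluster_area_nm2: 900.0           # single-channel footprint; smaller regions dropped
  connectivity: 8
  cru_threshold_nm: 150.0               # strict < threshold, single linkage
  pixel_size_nm: 5.0
  channel_footprint_nm2: 900.0

dataset:
  n_animals_per_group: 5
  cells_per_animal: 6
  animal_rel_sd: 0.05

compare:
  metrics: [mean_area_nm2, mean_channels, mean_nnd_nm, density_per_um2,
            mean_clusters_per_cru, mean_channels_per_cru]
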