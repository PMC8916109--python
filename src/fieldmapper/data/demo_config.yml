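# Demo-scale end-to-end configuration: a 2x2-tile synthetic domain with
# 10x-coarsened pixels (0.00025 deg), 12 scene dates across two seasons and
# four simulated labellers of mixed skill.
seed: 7
grid:
  pixel_size: 0.00025
  n_tiles_x: 2
  n_tiles_y: 2
seasons:
  growing: {start: 2018-05-01, end: 2018-09-30}
  dry: {start: 2018-11-15, end: 2019-02-15}
fixtures:
  n_dates_per_season: 6
  cloud_fraction: 0.25
  shadow_fraction: 0.08
  noise_sigma: 0.01
  landscape:
    cropland_fraction: 0.3
    fields_per_tile: 64
labeling:
  skills: [1.0, 0.7, 0.6, 0.5]
  qa_cells: 4
  beta: [0.3, 0.1, 0.2, 0.2, 0.2]
learning:
  starter_cells: 40
  validation_cells: 50
  cells_per_iteration: 20
  max_iterations: 2
  pixels_per_cell: 40
segmentation:
  n_segments: 400
  merge_threshold: 0.05
  compactness: 0.01
assessment:
  n_reference_points: 400
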