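# End-to-end demo: two simulated groups, small scenes, full pipeline.
psf:
  n_beads: 9
  noise_level: 100.0
scene:
  cell_area: 400.0
  pixel_size_xy: 0.1
  n_planes: 7
  noise_level: 200.0
pipeline:
  deconvolution_iterations: 5
  min_area: 0.1          # µm²
  max_area: 20.0         # µm²
  max_branch_points: 0
  min_solidity: 0.6
  collapse_half_window: 2
  threshold_method: otsu
groups:
  wt:
    n_cells: 3
    n_mitochondria: 20
    length_mean: 2.34
  null:
    n_cells: 3
    n_mitochondria: 32
    length_mean: 3.32
redox:
  n_cells: 3
  true_oxd:
    wt: 0.404
    null: 0.597
  r_red: 0.63
  r_ox: 1.35
  instrument_factor: 1.0
  noise_sd: 0.02
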