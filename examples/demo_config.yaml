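# Synthetic end-to-end demo: three WT compartments with known polarity,
# a blood-cell field, and gene lists with a designed overlap structure.
seed: 17

scene:
  width: 360
  height: 240
  pixel_size: 1.0
  background_level: 0.0
  noise_sd: 0.0
  compartments:
    - centroid: [60, 60]          # anti-polar: TBXT 180 deg from CER1
      radius: 35
      channel_levels: {mKate: 1.0, CER1: 0.2, TBXT: 0.2}
      polar_domains:
        - [CER1, 45, 30, 1.0]
        - [TBXT, 225, 30, 1.0]
      egfp_cover_fraction: 0.8
    - centroid: [180, 60]         # syn-polar: peaks 30 deg apart
      radius: 35
      channel_levels: {mKate: 1.0, CER1: 0.2, TBXT: 0.2}
      polar_domains:
        - [CER1, 90, 30, 1.0]
        - [TBXT, 120, 30, 1.0]
      egfp_cover_fraction: 0.4
    - centroid: [300, 60]         # unrelated: peaks 90 deg apart
      radius: 35
      channel_levels: {mKate: 1.0, CER1: 0.2, TBXT: 0.2}
      polar_domains:
        - [CER1, 10, 30, 1.0]
        - [TBXT, 100, 30, 1.0]
      egfp_cover_fraction: 0.0

segmentation:
  detect_channel: mKate
  max_compartment_area: 100.0
  single_cell_area: 96.0
  threshold: 0.5
  egfp_channel: EGFP
  egfp_threshold: 0.5

radial:
  depth: 12.0
  align_channel: CER1

polarity:
  threshold: 0.1
  window_fraction: 0.125

cells:
  n_cells: 120
  marker_model:
    CD43:   [0.9, 5.0, 0.5, 0.3]
    CD235a: [0.5, 5.0, 0.5, 0.3]
    CD42b:  [0.5, 5.0, 0.5, 0.3]
  clusters:
    - [100, 100, 8.0]
    - [400, 400, 8.0]

foci:
  positivity_thresholds: {CD43: 2.0, CD235a: 2.0, CD42b: 2.0}
  assessed_markers: [CD235a, CD42b]
  link_radius: 60.0

gene_lists:
  universe_size: 2000
  sizes: [60, 50, 55]
  overlap_design: [5, 20, 3]

stats:
  n_reps: 199
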