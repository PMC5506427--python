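# Two-marker senescence quantification in BJ fibroblasts: overlap of
# SA-β-gal positivity with loss of nuclear HMGB1.
# Injected joints: growing P(SA+)=4.1%, P(SA+ & HMGB1-)=3.88%;
# DIS P(SA+)=88.24%, P(SA+ & HMGB1-)=86.8%; marginal HMGB1+ 82.4% / 5.5%.
channels: [BF, DAPI, HMGB1]
image_size_px: 192
pixel_size_um: 0.5
doublet_fraction: 0.02
defocus_fraction: 0.02
populations:
  - name: growing
    n_cells: 600
    senescent_fraction: 0.041
    area_um2_mean: 461.0
    markers:
      HMGB1: {p_pos_given_sen: 0.0537, p_pos_given_nonsen: 0.857}
  - name: dis
    n_cells: 600
    senescent_fraction: 0.8824
    area_um2_mean: 668.9
    markers:
      HMGB1: {p_pos_given_sen: 0.0163, p_pos_given_nonsen: 0.345}
  - name: unstained
    n_cells: 400
    unstained: true
    area_um2_mean: 560.0
    markers:
      HMGB1: {p_pos_given_sen: 0.0, p_pos_given_nonsen: 0.0}
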