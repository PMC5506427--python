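# Bleomycin-treated lung cells stained for SA-β-gal, Ki67 and BrdU (after
# BrdU pulse): the SA-β-gal-positive cells are almost entirely
# proliferation-marker negative.  Injected conditionals:
# P(Ki67- | SA+) = 0.9912, P(BrdU- | SA+) = 0.98; markers conditionally
# independent given senescence, so P(Ki67- & BrdU- | SA+) = 0.9714 and
# P(Ki67- & BrdU- | SA-) = 0.236^2 = 0.0557.
channels: [BF, DAPI, Ki67, BrdU]
image_size_px: 128
pixel_size_um: 0.5
doublet_fraction: 0.02
defocus_fraction: 0.02
populations:
  - name: bleomycin
    n_cells: 1400
    senescent_fraction: 0.09
    area_um2_mean: 120.0
    markers:
      Ki67: {p_pos_given_sen: 0.0088, p_pos_given_nonsen: 0.764}
      BrdU: {p_pos_given_sen: 0.02, p_pos_given_nonsen: 0.764}
  - name: unstained
    n_cells: 400
    unstained: true
    area_um2_mean: 120.0
    markers:
      Ki67: {p_pos_given_sen: 0.0, p_pos_given_nonsen: 0.0}
      BrdU: {p_pos_given_sen: 0.0, p_pos_given_nonsen: 0.0}
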