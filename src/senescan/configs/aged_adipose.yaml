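# Subcutaneous adipose-tissue-derived stromal cells from young (2-month) and
# old (24-month) mice: SA-β-gal-positive fractions 1.4% vs 13.8%.  Senescent
# cells are rendered larger than nonsenescent ones (size means are config
# choices; only the direction of the shift is a study observation).
channels: [BF, DAPI]
image_size_px: 128
pixel_size_um: 0.5
doublet_fraction: 0.02
defocus_fraction: 0.02
populations:
  - name: young
    n_cells: 900
    senescent_fraction: 0.014
    area_um2_mean: 110.0
    area_um2_mean_senescent: 180.0
  - name: old
    n_cells: 900
    senescent_fraction: 0.138
    area_um2_mean: 110.0
    area_um2_mean_senescent: 180.0
  - name: unstained
    n_cells: 400
    unstained: true
    area_um2_mean: 110.0
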