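# Dissociated subcutaneous tumors of GFP-tagged, tet-off shp53 transformed
# MEFs: p53 restoration (+Dox) drives tumor-cell senescence.  Channels
# distinguish GFP+ tumor cells from CD45+ immune cells; a viability-dye
# channel gates live cells.  Injected values: tumor cells 69.8% (+Dox) vs
# 2.4% (untreated) SA-β-gal positive; viability 95% vs 96.9%.  Immune-cell
# SA+ fractions (small elevation under Dox) are config choices: 4% vs 2%.
channels: [BF, DAPI, GFP, CD45, LiveDead]
image_size_px: 128
pixel_size_um: 0.5
doublet_fraction: 0.02
defocus_fraction: 0.02
populations:
  - name: dox
    n_cells: 800
    viable_fraction: 0.95
    area_um2_mean: 150.0
    cell_types:
      tumor:
        prob: 0.75
        senescent_fraction: 0.698
        channel_levels: {GFP: 120.0, CD45: 3.0}
      immune:
        prob: 0.25
        senescent_fraction: 0.04
        area_um2_mean: 80.0
        channel_levels: {CD45: 120.0, GFP: 3.0}
  - name: untreated
    n_cells: 800
    viable_fraction: 0.969
    area_um2_mean: 150.0
    cell_types:
      tumor:
        prob: 0.75
        senescent_fraction: 0.024
        channel_levels: {GFP: 120.0, CD45: 3.0}
      immune:
        prob: 0.25
        senescent_fraction: 0.02
        area_um2_mean: 80.0
        channel_levels: {CD45: 120.0, GFP: 3.0}
  - name: unstained
    n_cells: 400
    unstained: true
    viable_fraction: 0.95
    area_um2_mean: 150.0
    cell_types:
      tumor:
        prob: 0.75
        channel_levels: {GFP: 120.0, CD45: 3.0}
      immune:
        prob: 0.25
        area_um2_mean: 80.0
        channel_levels: {CD45: 120.0, GFP: 3.0}
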