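# Dissociated lungs, bleomycin-induced fibrosis vs untreated controls.
# pCK marks epithelial cells, CD45 immune cells.  Injected SA-β-gal-positive
# fractions: epithelial 8.96% (bleomycin) vs 1.14% (control); immune 15.3%
# vs 16.11%.  The "other" stromal compartment (no identity marker) uses
# config-chosen fractions.
channels: [BF, DAPI, CD45, pCK]
image_size_px: 128
pixel_size_um: 0.5
doublet_fraction: 0.02
defocus_fraction: 0.02
populations:
  - name: bleomycin
    n_cells: 900
    area_um2_mean: 120.0
    cell_types:
      epithelial:
        prob: 0.3
        senescent_fraction: 0.0896
        area_um2_mean: 150.0
        channel_levels: {pCK: 120.0, CD45: 3.0}
      immune:
        prob: 0.5
        senescent_fraction: 0.153
        area_um2_mean: 80.0
        channel_levels: {CD45: 120.0, pCK: 3.0}
      other:
        prob: 0.2
        senescent_fraction: 0.05
        channel_levels: {CD45: 3.0, pCK: 3.0}
  - name: control
    n_cells: 900
    area_um2_mean: 120.0
    cell_types:
      epithelial:
        prob: 0.3
        senescent_fraction: 0.0114
        area_um2_mean: 150.0
        channel_levels: {pCK: 120.0, CD45: 3.0}
      immune:
        prob: 0.5
        senescent_fraction: 0.1611
        area_um2_mean: 80.0
        channel_levels: {CD45: 120.0, pCK: 3.0}
      other:
        prob: 0.2
        senescent_fraction: 0.03
        channel_levels: {CD45: 3.0, pCK: 3.0}
  - name: unstained
    n_cells: 400
    unstained: true
    area_um2_mean: 120.0
    cell_types:
      epithelial:
        prob: 0.3
        area_um2_mean: 150.0
        channel_levels: {pCK: 120.0, CD45: 3.0}
      immune:
        prob: 0.5
        area_um2_mean: 80.0
        channel_levels: {CD45: 120.0, pCK: 3.0}
      other:
        prob: 0.2
        channel_levels: {CD45: 3.0, pCK: 3.0}
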