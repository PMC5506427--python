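# Dissociated-tissue hierarchy: DAPI singlets -> focused -> live ->
# cell type (GFP+ tumor / CD45+GFP- immune) -> SA-β-gal per type.
# Cell-type and viability cutoffs are fixed (well-separated populations);
# the SA-β-gal gate is referenced to the unstained control.
gates:
  - {name: singlets, type: singlet_dapi}
  - {name: focused, type: focus, parent: singlets}
  - {name: live, type: threshold, parent: focused,
     feature: mean_pixel_LiveDead, direction: below, cutoff: 50}
  - {name: gfp_pos, type: threshold, parent: live,
     feature: mean_pixel_GFP, direction: above, cutoff: 25}
  - {name: gfp_neg, type: boolean, parent: live, op: NOT, gates: [gfp_pos]}
  - {name: cd45_pos, type: threshold, parent: live,
     feature: mean_pixel_CD45, direction: above, cutoff: 25}
  - {name: tumor, type: boolean, parent: live, op: AND, gates: [gfp_pos]}
  - {name: immune, type: boolean, parent: live, op: AND, gates: [cd45_pos, gfp_neg]}
  - {name: sa_pos_tumor, type: control_threshold, parent: tumor,
     feature: bf_mean_pixel, direction: below, quantile: 0.01}
  - {name: sa_pos_immune, type: control_threshold, parent: immune,
     feature: bf_mean_pixel, direction: below, quantile: 0.01}
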