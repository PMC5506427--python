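gates:
  - {name: singlets, type: singlet_dapi}
  - {name: focused, type: focus, parent: singlets}
  - {name: pck_pos, type: threshold, parent: focused,
     feature: mean_pixel_pCK, direction: above, cutoff: 25}
  - {name: cd45_pos, type: threshold, parent: focused,
     feature: mean_pixel_CD45, direction: above, cutoff: 25}
  - {name: cd45_neg, type: boolean, parent: focused, op: NOT, gates: [cd45_pos]}
  - {name: epithelial, type: boolean, parent: focused, op: AND,
     gates: [pck_pos, cd45_neg]}
  - {name: immune, type: boolean, parent: focused, op: AND, gates: [cd45_pos]}
  - {name: sa_pos_epithelial, type: control_threshold, parent: epithelial,
     feature: bf_mean_pixel, direction: below, quantile: 0.01}
  - {name: sa_pos_immune, type: control_threshold, parent: immune,
     feature: bf_mean_pixel, direction: below, quantile: 0.01}
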