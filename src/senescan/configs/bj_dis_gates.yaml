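# Hierarchy: BF singlets -> focused -> marker gates referenced to the
# unstained control (SA-β-gal positivity = low BF mean pixel).
gates:
  - {name: singlets, type: singlet_bf, min_ar: 0.6, area: [50, 5000]}
  - {name: focused, type: focus, parent: singlets, min_grms: 2.0}
  - {name: sa_pos, type: control_threshold, parent: focused,
     feature: bf_mean_pixel, direction: below, quantile: 0.01}
  - {name: sa_neg, type: boolean, parent: focused, op: NOT, gates: [sa_pos]}
  - {name: gh2ax_pos, type: threshold, parent: focused,
     feature: spot_count, direction: above, cutoff: 2.5}
  - {name: hmgb1_pos, type: control_threshold, parent: focused,
     feature: mean_pixel_HMGB1, direction: above, quantile: 0.99}
  - {name: hmgb1_neg, type: boolean, parent: focused, op: NOT, gates: [hmgb1_pos]}
  - {name: senescent, type: boolean, parent: focused, op: AND,
     gates: [sa_pos, hmgb1_neg]}
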