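# Conditional statistics within the small SA-β-gal-positive subset are
# sensitive to false-positive contamination, so the SA gate here is a fixed
# manual cutoff placed in the valley between the unstained and stained
# bright-field modes (the equivalent of a visually verified gate); the modes
# are separated by many standard deviations, so placement is not critical.
gates:
  - {name: singlets, type: singlet_dapi}
  - {name: focused, type: focus, parent: singlets}
  - {name: sa_pos, type: threshold, parent: focused,
     feature: bf_mean_pixel, direction: below, cutoff: -100}
  - {name: sa_neg, type: boolean, parent: focused, op: NOT, gates: [sa_pos]}
  - {name: ki67_pos, type: control_threshold, parent: focused,
     feature: max_pixel_Ki67, direction: above, quantile: 0.99}
  - {name: ki67_neg, type: boolean, parent: focused, op: NOT, gates: [ki67_pos]}
  - {name: brdu_pos, type: control_threshold, parent: focused,
     feature: mean_pixel_BrdU, direction: above, quantile: 0.99}
  - {name: brdu_neg, type: boolean, parent: focused, op: NOT, gates: [brdu_pos]}
  - {name: sa_pos_nonprolif, type: boolean, parent: focused, op: AND,
     gates: [sa_pos, ki67_neg, brdu_neg]}
  - {name: sa_neg_nonprolif, type: boolean, parent: focused, op: AND,
     gates: [sa_neg, ki67_neg, brdu_neg]}
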