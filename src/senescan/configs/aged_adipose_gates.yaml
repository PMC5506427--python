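gates:
  - {name: singlets, type: singlet_dapi}
  - {name: focused, type: focus, parent: singlets}
  - {name: sa_pos, type: control_threshold, parent: focused,
     feature: bf_mean_pixel, direction: below, quantile: 0.01}
  - {name: sa_neg, type: boolean, parent: focused, op: NOT, gates: [sa_pos]}
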