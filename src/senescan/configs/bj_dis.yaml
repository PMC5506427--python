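# Etoposide-induced senescent (DIS) vs normally growing human BJ fibroblasts,
# X-gal (SA-β-gal) stained, with DAPI, gH2AX foci and nuclear HMGB1 channels.
# Population values: 89.6% / 4.8% SA-β-gal positive; 28.3% / 7.8% gH2AX focus
# positive; mean cell areas 668.9 / 461 um^2; nuclear HMGB1 positivity
# 5.5% / 82.4%.  An unstained aliquot serves as the gating reference.
channels: [BF, DAPI, gH2AX, HMGB1]
image_size_px: 192
pixel_size_um: 0.5
doublet_fraction: 0.02
defocus_fraction: 0.02
populations:
  - name: growing
    n_cells: 600
    senescent_fraction: 0.048
    area_um2_mean: 461.0
    area_cv: 0.25
    foci: {pos_fraction: 0.078, min_pos: 3, mean_extra: 3.0, mean_neg: 0.3}
    markers:
      HMGB1: {p_pos_given_sen: 0.05, p_pos_given_nonsen: 0.863}
  - name: dis
    n_cells: 600
    senescent_fraction: 0.896
    area_um2_mean: 668.9
    area_cv: 0.25
    foci: {pos_fraction: 0.283, min_pos: 3, mean_extra: 3.0, mean_neg: 0.3}
    markers:
      HMGB1: {p_pos_given_sen: 0.016, p_pos_given_nonsen: 0.391}
  - name: unstained
    n_cells: 400
    unstained: true
    area_um2_mean: 560.0
    area_cv: 0.25
    foci: {pos_fraction: 0.15, min_pos: 3, mean_extra: 3.0, mean_neg: 0.3}
    markers:
      HMGB1: {p_pos_given_sen: 0.0, p_pos_given_nonsen: 0.0}
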