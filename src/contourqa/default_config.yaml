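# Default cohort-model configuration.
#
# The femoral-head fixed thresholds were calibrated once on the synthetic
# femoral phantoms (ball IS extent <= ~34 mm, ball+shaft IS extent >= ~104 mm;
# both shapes have near-symmetric in-plane footprints) and are deliberately
# conservative midpoints.
models:
  bladder:
    volume_percentile: 25.0        # bottom quartile is the "initial condition"
    ratio_low_percentile: 10.0
    ratio_high_percentile: 90.0
  femoral_head:
    volume_percentile: 20.0
    is_range_mm_threshold: 60.0    # mm; between ball-only and ball+shaft IS extents
    lr_over_ap_ratio_threshold: 1.5
  slice_extent:
    percentile: 90.0
    combine: and                   # require both LR and AP range-of-ranges extreme
  percentile_method: linear        # interpolation between closest ranks
  min_cohort_size: 8
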