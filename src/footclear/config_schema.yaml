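# footclear analysis configuration schema.
# Every key is optional; values shown are the defaults.

laser:                         # automatic laser-dot detection
  brightness_quantile: 0.999   # intensity quantile for the bright-pixel threshold
  min_area: 3                  # blob area bounds, px^2
  max_area: 400
  min_circularity: 0.6         # 4*pi*A/P^2 cutoff
  max_column_offset: 12        # max horizontal offset of the dot pair, px
  expected_separation_range: [30, 600]   # plausible dot separation, px

detection:                     # classical background-subtraction backend
  diff_threshold: 30           # |frame - reference| intensity threshold
  min_area: 500                # minimum silhouette area, px^2

occlusion:                     # swing-foot recovery during overlap
  rotation_range_deg: 20       # search +/- this rotation
  rotation_step_deg: 5
  translation_window_px: [40, 15]   # +/- columns, +/- rows
  edge_gradient_threshold: null     # null -> Otsu on the gradient magnitude

trajectory:                    # stride segmentation
  stationary_velocity_px: 0.5  # |centroid velocity| below this is stationary
  median_window: 3             # velocity median-smoothing window, frames
  min_bad_run: 3               # sustained frames needed to cut a stride
  min_points: 8                # minimum points for a quintic fit

pipeline:
  laser_distance_mm: 164       # physical inter-laser distance D
  mfc_method: fitted_curve     # fitted_curve | raw_series
  laser_min_hits: 3            # early-stop bookkeeping for the laser scan
  laser_miss_patience: 2
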