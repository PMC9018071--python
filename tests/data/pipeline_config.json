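{
  "calibration": {
    "intercept": 0.0,
    "model": "linear",
    "slope": 4.0
  },
  "doubling_time_min": 288.0,
  "doubling_times": {
    "snf1_adk1": 288.0,
    "wild_type": 216.0
  },
  "error_threshold_sd": 5.0,
  "error_window": 7,
  "foci_tolerance": 4000.0,
  "min_predip_span": 92.0,
  "rmsd_horizon": 180.0,
  "rmsd_step": 30.0,
  "seed": 42,
  "synthetic": {
    "agg_corr_target": 0.99,
    "agg_intercept": 500.0,
    "agg_slope": 2.0,
    "baseline_atp": 4.0,
    "baseline_ratio": 1.0,
    "cell_background": 500.0,
    "cell_radius": 8,
    "channel_base_490": 2000.0,
    "dip_depth_range": [
      0.56,
      0.85
    ],
    "dip_duration": 15.0,
    "dip_rate": 0.1,
    "focus_amplitude": 10000.0,
    "frame_error_magnitude": 8.0,
    "frame_error_rate": 0.014285714285714285,
    "frame_interval": 4.0,
    "image_background": 100.0,
    "image_size": 128,
    "mix": {
      "dip": 0.2,
      "oscillating": 0.0,
      "shallow_dip": 0.05,
      "shift": 0.1,
      "stable": 0.65
    },
    "n_cells": 200,
    "n_frames": 150,
    "osc_amplitude": 0.15,
    "osc_period": 35.0,
    "pixel_noise_sd": 0.0,
    "pixel_poisson": false,
    "post_dip_fold": 5.6,
    "post_dip_fold_spread": 0.25,
    "post_dip_horizon": 180.0,
    "psf_sigma": 1.5,
    "ratio_noise_sd": 0.05,
    "seed": 0,
    "shallow_depth_range": [
      0.36,
      0.44
    ],
    "shift_prob": 0.1
  },
  "thresholds": {
    "baseline_window": 5,
    "deep": 0.5,
    "enter_delta": 0.2,
    "exit_frac": 0.1,
    "min_frames": 2,
    "shallow": 0.33
  }
}
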