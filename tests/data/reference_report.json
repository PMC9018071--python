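{
  "classification_fractions": {
    "dip": 0.19,
    "shallow_dip": 0.07,
    "shift": 0.11,
    "stable": 0.63
  },
  "config_hash": "0dc39d61c7baf7c2",
  "correction_rate": 0.0161,
  "foci_summary": {
    "n_cells_in_field": 8,
    "n_cells_with_foci_planted": 4,
    "n_fields": 1,
    "pct_cells_with_foci": 50.0
  },
  "n_cells": 200,
  "n_classified": 200,
  "n_corrected_frames": 483,
  "n_frames": 150,
  "period_summary": {
    "median_period_min": 56.0,
    "n_significant": 7
  },
  "population_atp": {
    "cv": 0.1089804611417537,
    "mean": 3.8535352091651616,
    "n": 200,
    "sd": 0.4199600441208036
  },
  "population_ratio": {
    "cv": 0.1089804611417537,
    "mean": 0.9633838022912904,
    "n": 200,
    "sd": 0.1049900110302009
  },
  "reference_error_rate": 0.014285714285714285,
  "rmsd_summary": {
    "frac_fold_gt3": 1.0,
    "mean_max_fold": 6.0854610811604815,
    "median_max_fold": 5.6617450534511224,
    "n_dip_cells": 38,
    "n_skipped_short_predip": 0,
    "n_stable_cells": 126
  },
  "seed": 42,
  "version": "0.1.0"
}
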