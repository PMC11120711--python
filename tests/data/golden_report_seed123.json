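{
 "confusion_metrics": {
  "any_driver_at_fixed_803_kpa": {
   "accuracy": 0.777778,
   "fn": 2,
   "fp": 10,
   "sensitivity": 0.916667,
   "specificity": 0.666667,
   "threshold": 803.0,
   "tn": 20,
   "tp": 22
  },
  "kras_at_fixed_850_kpa": {
   "accuracy": 0.777778,
   "fn": 3,
   "fp": 9,
   "sensitivity": 0.85,
   "specificity": 0.735294,
   "threshold": 850.0,
   "tn": 25,
   "tp": 17
  },
  "pattern_marker_complex_tubular": {
   "accuracy": 0.333333,
   "fn": 13,
   "fp": 23,
   "sensitivity": 0.458333,
   "specificity": 0.233333,
   "threshold": "complex_tubular",
   "tn": 7,
   "tp": 11
  },
  "pattern_marker_solid": {
   "accuracy": 0.666667,
   "fn": 14,
   "fp": 4,
   "sensitivity": 0.416667,
   "specificity": 0.866667,
   "threshold": "solid",
   "tn": 26,
   "tp": 10
  }
 },
 "counting": {
  "driver_mutation_cases_pct": 43.478261,
  "driver_mutation_rois_pct": 44.444444,
  "kras_cases_pct": 34.782609,
  "kras_rois_pct": 37.037037,
  "n_cases": 46,
  "n_rois": 54
 },
 "fisher_tests": {
  "grade_high_vs_low": {
   "p_two_sided": 0.00729,
   "table": [
    [
     10,
     3
    ],
    [
     10,
     23
    ]
   ]
  },
  "pattern_solid_vs_tubular": {
   "p_two_sided": 0.023682,
   "table": [
    [
     10,
     4
    ],
    [
     11,
     23
    ]
   ]
  }
 },
 "provenance": {
  "seed": 123
 },
 "roc_results": {
  "any_driver": {
   "auc": 0.909722,
   "n_negative": 30,
   "n_positive": 24,
   "youden_j": 0.775,
   "youden_threshold_kpa": 869.313501
  },
  "kras": {
   "auc": 0.829412,
   "n_negative": 34,
   "n_positive": 20,
   "youden_j": 0.673529,
   "youden_threshold_kpa": 870.498216
  }
 },
 "schema_version": 1
}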