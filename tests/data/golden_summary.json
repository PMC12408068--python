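{
 "clusters": {
  "mean_peak_logfc": {
   "1": 0.277414,
   "2": 0.442994,
   "3": -0.037018,
   "4": -0.031279
  },
  "mean_speckle_signal": {
   "1": 1.409582,
   "2": 3.4423,
   "3": 1.323749,
   "4": 0.994768
  },
  "n_selected_genes": 20,
  "sizes": {
   "1": 10,
   "2": 6,
   "3": 2,
   "4": 2
  }
 },
 "fraction_looping": 0.885417,
 "highly_looping": {
  "cutoff_count": 3.0,
  "cutoff_rank": 84,
  "n_flagged": 11
 },
 "loops": {
  "logfc_other_mean": -0.081382,
  "logfc_specific_mean": 0.366765,
  "mannwhitney_p": 0.026563,
  "n_passed_filters": 138,
  "n_total": 148
 },
 "n_condition_specific_peaks": 16,
 "pileup": {
  "all": {
   "center_log2_mean_oe": 0.004415,
   "n_blacklisted": 4,
   "n_deduplicated": 13,
   "n_dropped_edge": 7,
   "n_used": 72
  },
  "highly": {
   "center_log2_mean_oe": 0.018281,
   "n_blacklisted": 1,
   "n_deduplicated": 1,
   "n_dropped_edge": 0,
   "n_used": 9
  },
  "specific": {
   "center_log2_mean_oe": -0.036086,
   "n_blacklisted": 1,
   "n_deduplicated": 4,
   "n_dropped_edge": 0,
   "n_used": 11
  },
  "speckle": {
   "center_log2_mean_oe": 0.010106,
   "n_blacklisted": 2,
   "n_deduplicated": 10,
   "n_dropped_edge": 0,
   "n_used": 19
  }
 },
 "seed": 29,
 "signal": {
  "decile_median_logcpm": [
   12.429222,
   12.593233,
   12.583262,
   12.417633,
   12.732098,
   12.493762,
   12.712659,
   12.888438,
   12.877852,
   12.895864
  ],
  "n_speckle_associated": 31,
  "pearson_r_logcpm_vs_signal": 0.389526,
  "speckle_threshold": 2.81357
 },
 "thresholds": {
  "cpm_pseudocount": 0.5,
  "de_lfc_min": 0.5,
  "de_padj_max": 0.05,
  "diff_fdr_max": 0.01,
  "diff_min_total_pets": 8,
  "diff_strong_pets": 5,
  "kmeans_k": 4,
  "kmeans_restarts": 10,
  "loop_fdr_max": 0.01,
  "loop_min_pets": 5,
  "pileup_half_width": 10,
  "speckle_percentile": 90.0
 }
}
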