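{
 "n_per_group": 4,
 "n_background": 8,
 "n_markers": 2,
 "marker_mean_abundance": 0.005,
 "marker_sigma": 0.4,
 "marker_presence_prob": 0.9,
 "relative_presence": 0.5,
 "marker_fold_change": 0.2,
 "background_concentration": 50.0,
 "branch_scale": 1.0,
 "t_s": 0.92,
 "d_f": 0.11,
 "sim_range": [
  0.93,
  0.98
 ],
 "seed": 42
}
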