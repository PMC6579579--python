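{
  "dimer_percentages": {
    "V5_untreated": 11.23,
    "V5_benzonase": 7.60,
    "FLAG_untreated": 5.19,
    "FLAG_benzonase": 6.47
  },
  "bound_fractions_pct": {"C59": 48.9, "C87": 49.3},
  "chipseq_peak_counts": {"wild_type": 68077, "double_knock_in": 74374},
  "cell_cycle_fractions": {"g1": 0.102, "s": 0.739, "g2": 0.159},
  "genome_size_mb": 2716,
  "engaged_fraction": 0.398,
  "genome_copies": 3,
  "method_estimates": {
    "mESC_CTCF": {"C59": 215200, "C87": 219200},
    "U2OS_CTCF": {"gel": 104900, "fcs_imaging": 114600},
    "mESC_Rad21": {"gel": 86900, "fcm": 131800}
  },
  "expected": {
    "occupancy": 0.499,
    "density_molecules_per_mb": 5.34,
    "density_units_per_mb_paired": 2.67,
    "dimer_mean_pct": 7.62,
    "dimer_std_pct": 2.6,
    "bound_mean_pct": 49.1,
    "sites_haploid": 71200,
    "sites_total": 213600,
    "final_mESC_CTCF": 217200,
    "final_U2OS_CTCF": 109800,
    "final_mESC_Rad21": 109400,
    "genome_copies": 3
  }
}
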