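{
  "proteins": {"total_identified": 798, "fdr01_identified": 624,
               "venn": {"common": 745, "exclusive_rrd": 22, "exclusive_control": 31}},
  "n_termini": {"venn": {"common": 457, "exclusive_rrd": 182, "exclusive_control": 216}},
  "c_termini": {"venn": {"common": 149, "exclusive_rrd": 46, "exclusive_control": 130}},
  "deps_reported": {"total": 93, "up": 52, "down": 41},
  "dep_thresholds": {"log2fc": 0.57, "p_mod": 0.05, "q_mod": 0.05}
}
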