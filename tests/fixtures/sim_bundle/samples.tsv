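rep1	rep1_stats/region_summary.tsv	kd1
rep2	rep2_stats/region_summary.tsv	kd1
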