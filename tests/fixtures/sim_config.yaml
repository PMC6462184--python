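# default simulation: three loci on a 1.2 kb toy contig, knockdown design
seed: 42
chrom: chrSim
genome_length: 1200
regions:
- [t1, 100, 400, +, target]
- [t2, 500, 800, '-', target]
- [kd1, 900, 1150, +, knockdown]
expected_reads: 60.0
length_distribution: {21: 0.1, 22: 0.2, 23: 0.4, 24: 0.2, 25: 0.1}
antisense_fraction: 0.2
clip3_prob: 0.15
clip3_max_len: 3
clip3_alphabet_bias: {A: 0.4, C: 0.1, G: 0.1, T: 0.4}
knockdown_spike: 0
depth_scale: 1.0
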