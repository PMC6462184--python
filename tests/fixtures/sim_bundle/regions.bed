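chrSim	100	400	t1	0	+	target
chrSim	500	800	t2	0	-	target
chrSim	900	1150	kd1	0	+	knockdown
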