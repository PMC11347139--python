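chrSyn	999	1000	site	100	+	5.2	31.0	0.001
chrSyn	1999	2000	site	100	-	1.1	2.0	0.4
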