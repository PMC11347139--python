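chrom	start_loc	end_loc	ref	strand	oddR	adjPval
chrSyn	999	1000	A	+	5.0	0.001
chrSyn	1999	2000	C	-	1.2	0.001
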