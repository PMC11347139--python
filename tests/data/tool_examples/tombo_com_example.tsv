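chrom	pos	strand	frac_modified
chrSyn	999	+	0.9
chrSyn	1999	-	0.2
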