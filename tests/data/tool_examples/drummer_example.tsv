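chromosome	pos	ref_base	strand	odds_ratio	padj
chrSyn	1000	A	+	4.2	0.001
chrSyn	2000	T	-	1.0	0.9
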