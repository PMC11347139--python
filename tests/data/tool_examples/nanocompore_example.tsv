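pos	chr	strand	ref_kmer	GMM_logit_pvalue
999	chrSyn	+	GGAGG	0.0005
1999	chrSyn	-	CCTCC	0.5
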