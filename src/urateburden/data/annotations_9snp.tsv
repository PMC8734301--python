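rs_id	gene	variant_class	allele_a	allele_b	risk_allele	effect_direction	effect_note
rs1183201	SLC17A1	intronic	A	T	T	lowers_urate	effect allele A is protective in EUR; beta=-0.062
rs12129861	PDZK1	intergenic	C	T	C	lowers_urate	effect allele T lowers serum urate in EUR; beta=-0.06
rs17300741	SLC22A11	intronic	A	G	A	raises_urate	renal urate under-excretion; beta=0.062
rs2231142	ABCG2	missense	G	T	T	raises_urate	Q141K; ~50% reduced ABCG2 transport activity; urate under-excretion
rs2242206	SLC16A9	missense	G	T	T	lowers_urate	K258T; renal overload gout OR=1.28
rs505802	SLC22A12	intergenic	C	T	C	lowers_urate	effect allele T lowers serum urate in EUR; beta=-0.056
rs734553	SLC2A9	intronic	G	T	T	raises_urate	altered GLUT9 urate affinity; raises gout risk
rs742132	LRRC16A	intronic	A	G	A	raises_urate	A allele raises serum urate in EUR; beta=0.054
rs780094	GCKR	intronic	C	T	T	raises_urate	glucose/lipid metabolism link; serum urate beta=0.052
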