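rs_id	allele_a	allele_b	count_a	count_b
rs1183201	A	T	464	542
rs12129861	C	T	544	462
rs17300741	A	G	465	541
rs2231142	G	T	911	95
rs2242206	G	T	738	268
rs505802	C	T	295	711
rs734553	G	T	246	760
rs742132	A	G	694	312
rs780094	C	T	593	413
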