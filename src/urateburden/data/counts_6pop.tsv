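rs_id	population	n_aa	n_ab	n_bb	n_missing
rs1183201	Filipino	7	59	109	.
rs1183201	Japanese	7	49	128	.
rs1183201	Korean	1	24	64	.
rs1183201	Native Hawaiian	17	64	63	.
rs1183201	Marshallese	35	65	18	.
rs1183201	Samoan	12	79	90	.
rs12129861	Filipino	71	9	89	.
rs12129861	Japanese	87	4	91	.
rs12129861	Korean	44	4	33	.
rs12129861	Native Hawaiian	49	8	78	.
rs12129861	Marshallese	43	4	67	.
rs12129861	Samoan	72	15	84	.
rs17300741	Filipino	128	41	5	.
rs17300741	Japanese	129	47	4	.
rs17300741	Korean	73	17	1	.
rs17300741	Native Hawaiian	75	51	13	.
rs17300741	Marshallese	64	39	17	.
rs17300741	Samoan	112	57	10	.
rs2231142	Filipino	51	92	36	.
rs2231142	Japanese	106	66	15	.
rs2231142	Korean	52	29	11	.
rs2231142	Native Hawaiian	110	33	2	.
rs2231142	Marshallese	83	35	4	.
rs2231142	Samoan	89	73	20	.
rs2242206	Filipino	59	79	41	.
rs2242206	Japanese	31	101	51	.
rs2242206	Korean	14	47	31	.
rs2242206	Native Hawaiian	50	58	36	.
rs2242206	Marshallese	38	56	25	.
rs2242206	Samoan	60	101	21	.
rs505802	Filipino	112	63	8	.
rs505802	Japanese	126	52	8	.
rs505802	Korean	59	30	4	.
rs505802	Native Hawaiian	52	77	16	.
rs505802	Marshallese	110	10	1	.
rs505802	Samoan	90	72	22	.
rs734553	Filipino	0	4	172	.
rs734553	Japanese	0	2	183	.
rs734553	Korean	0	3	90	.
rs734553	Native Hawaiian	2	22	119	.
rs734553	Marshallese	0	0	121	.
rs734553	Samoan	0	6	176	.
rs742132	Filipino	88	75	17	.
rs742132	Japanese	116	59	11	.
rs742132	Korean	55	32	4	.
rs742132	Native Hawaiian	44	83	19	.
rs742132	Marshallese	62	44	14	.
rs742132	Samoan	46	96	40	.
rs780094	Filipino	57	83	39	.
rs780094	Japanese	35	86	65	.
rs780094	Korean	33	41	18	.
rs780094	Native Hawaiian	60	70	14	.
rs780094	Marshallese	50	56	15	.
rs780094	Samoan	88	78	17	.
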