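sample	species	country	total	protein	protein_nonsyn	rrna	trna
B2470B1	body	China	35	30	20	1	4
B2471H5	head	China	32	22	11	0	10
B2557B	body	France	32	15	10	3	14
B2557H	head	France	27	12	8	6	9
B2558B	body	France	21	8	6	4	9
B2558H	head	France	19	9	6	0	10
B2516B2	body	Ethiopia	67	58	10	3	6
B2516H2	head	Ethiopia	50	47	3	0	3
B2560B	body	Ethiopia	17	9	6	2	6
B2560H	head	Ethiopia	65	56	9	1	8
B2563B2	body	Ethiopia	76	69	13	1	6
B2563H	head	Ethiopia	53	39	20	0	14
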