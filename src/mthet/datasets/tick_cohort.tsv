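sample	country	total	protein	protein_nonsyn	rrna	trna
Haemaphysalis formosensis	Japan	6	6	1	0	0
Haemaphysalis parva	Romania	6	5	4	0	1
Rhipicephalus microplus	Cambodia	40	34	3	0	6
Amblyomma cajennense	Brazil	166	136	33	22	8
Argas sp.	Springbok	11	10	0	1	0
Rhipicephalus geigyi	Burkina Faso	8	7	5	0	1
Otobius megnini	Madagascar	24	23	17	1	0
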