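sample	B2471H5	B2557B	B2557H	B2558B	B2558H	B2516B2	B2516H2	B2560B	B2560H	B2563B2	B2563H
B2470B1	0	0	0	0	2	5	1	0	0	1	6
B2471H5		0	2	1	3	5	2	0	0	2	6
B2557B			3	0	5	3	0	1	0	2	11
B2557H				3	5	4	0	1	0	3	7
B2558B					2	2	0	0	0	1	10
B2558H						3	0	0	0	2	9
B2516B2							13	11	14	55	0
B2516H2								0	21	1	1
B2560B									0	0	2
B2560H										1	1
B2563B2											2
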