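sample	gene	sites	nonsynonymous
B2470B1	atp8-atp6	1	1
B2470B1	cytb	3	2
B2470B1	cox1	15	9
B2470B1	cox3	4	3
B2470B1	nad1	1	1
B2470B1	nad5	2	2
B2470B1	nad6	0	0
B2470B1	nad4L	0	0
B2470B1	nad4	3	2
B2470B1	nad2	0	0
B2470B1	nad3	0	0
B2470B1	cox2	1	0
B2470B1	rrnL	1
B2470B1	rrnS	0
B2470B1	tRNAs	4
B2471H5	atp8-atp6	2	2
B2471H5	cytb	0	0
B2471H5	cox1	8	2
B2471H5	cox3	0	0
B2471H5	nad1	0	0
B2471H5	nad5	7	4
B2471H5	nad6	1	1
B2471H5	nad4L	0	0
B2471H5	nad4	1	1
B2471H5	nad2	0	0
B2471H5	nad3	2	0
B2471H5	cox2	1	1
B2471H5	rrnL	0
B2471H5	rrnS	0
B2471H5	tRNAs	10
B2557B	atp8-atp6	2	2
B2557B	cytb	0	0
B2557B	cox1	2	2
B2557B	cox3	3	2
B2557B	nad1	0	0
B2557B	nad5	5	3
B2557B	nad6	0	0
B2557B	nad4L	1	0
B2557B	nad4	0	0
B2557B	nad2	0	0
B2557B	nad3	1	0
B2557B	cox2	1	1
B2557B	rrnL	2
B2557B	rrnS	1
B2557B	tRNAs	14
B2557H	atp8-atp6	0	0
B2557H	cytb	0	0
B2557H	cox1	2	1
B2557H	cox3	3	2
B2557H	nad1	0	0
B2557H	nad5	5	3
B2557H	nad6	1	1
B2557H	nad4L	0	0
B2557H	nad4	1	1
B2557H	nad2	0	0
B2557H	nad3	0	0
B2557H	cox2	0	0
B2557H	rrnL	3
B2557H	rrnS	3
B2557H	tRNAs	9
B2558B	atp8-atp6	1	1
B2558B	cytb	1	1
B2558B	cox1	1	1
B2558B	cox3	3	2
B2558B	nad1	0	0
B2558B	nad5	2	1
B2558B	nad6	0	0
B2558B	nad4L	0	0
B2558B	nad4	0	0
B2558B	nad2	0	0
B2558B	nad3	0	0
B2558B	cox2	0	0
B2558B	rrnL	2
B2558B	rrnS	2
B2558B	tRNAs	9
B2558H	atp8-atp6	1	1
B2558H	cytb	0	0
B2558H	cox1	0	0
B2558H	cox3	3	3
B2558H	nad1	0	0
B2558H	nad5	5	2
B2558H	nad6	0	0
B2558H	nad4L	0	0
B2558H	nad4	0	0
B2558H	nad2	0	0
B2558H	nad3	0	0
B2558H	cox2	0	0
B2558H	rrnL	0
B2558H	rrnS	0
B2558H	tRNAs	10
B2516B2	atp8-atp6	0	0
B2516B2	cytb	0	0
B2516B2	cox1	52	4
B2516B2	cox3	0	0
B2516B2	nad1	0	0
B2516B2	nad5	3	3
B2516B2	nad6	1	1
B2516B2	nad4L	0	0
B2516B2	nad4	1	1
B2516B2	nad2	0	0
B2516B2	nad3	0	0
B2516B2	cox2	1	1
B2516B2	rrnL	2
B2516B2	rrnS	1
B2516B2	tRNAs	6
B2516H2	atp8-atp6	0	0
B2516H2	cytb	0	0
B2516H2	cox1	45	1
B2516H2	cox3	2	2
B2516H2	nad1	0	0
B2516H2	nad5	0	0
B2516H2	nad6	0	0
B2516H2	nad4L	0	0
B2516H2	nad4	0	0
B2516H2	nad2	0	0
B2516H2	nad3	0	0
B2516H2	cox2	0	0
B2516H2	rrnL	0
B2516H2	rrnS	0
B2516H2	tRNAs	3
B2560B	atp8-atp6	0	0
B2560B	cytb	0	0
B2560B	cox1	4	1
B2560B	cox3	0	0
B2560B	nad1	0	0
B2560B	nad5	3	3
B2560B	nad6	1	1
B2560B	nad4L	0	0
B2560B	nad4	0	0
B2560B	nad2	0	0
B2560B	nad3	0	0
B2560B	cox2	1	1
B2560B	rrnL	2
B2560B	rrnS	0
B2560B	tRNAs	6
B2560H	atp8-atp6	0	0
B2560H	cytb	0	0
B2560H	cox1	54	9
B2560H	cox3	0	0
B2560H	nad1	0	0
B2560H	nad5	0	0
B2560H	nad6	0	0
B2560H	nad4L	0	0
B2560H	nad4	0	0
B2560H	nad2	0	0
B2560H	nad3	2	0
B2560H	cox2	0	0
B2560H	rrnL	0
B2560H	rrnS	1
B2560H	tRNAs	8
B2563B2	atp8-atp6	1	1
B2563B2	cytb	0	0
B2563B2	cox1	61	8
B2563B2	cox3	0	0
B2563B2	nad1	0	0
B2563B2	nad5	4	3
B2563B2	nad6	1	1
B2563B2	nad4L	0	0
B2563B2	nad4	0	0
B2563B2	nad2	0	0
B2563B2	nad3	1	0
B2563B2	cox2	1	1
B2563B2	rrnL	1
B2563B2	rrnS	0
B2563B2	tRNAs	6
B2563H	atp8-atp6	7	3
B2563H	cytb	0	0
B2563H	cox1	5	2
B2563H	cox3	6	4
B2563H	nad1	6	3
B2563H	nad5	0	0
B2563H	nad6	1	1
B2563H	nad4L	0	0
B2563H	nad4	8	4
B2563H	nad2	4	2
B2563H	nad3	1	0
B2563H	cox2	1	1
B2563H	rrnL	0
B2563H	rrnS	0
B2563H	tRNAs	14
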