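sample	gene	sites	nonsynonymous
Haemaphysalis formosensis	atp8-atp6	1	1
Haemaphysalis formosensis	cytb	5	0
Haemaphysalis formosensis	cox1	0	0
Haemaphysalis formosensis	cox2	0	0
Haemaphysalis formosensis	cox3	0	0
Haemaphysalis formosensis	nad1	0	0
Haemaphysalis formosensis	nad2	0	0
Haemaphysalis formosensis	nad3	0	0
Haemaphysalis formosensis	nad4	0	0
Haemaphysalis formosensis	nad4L	0	0
Haemaphysalis formosensis	nad5	0	0
Haemaphysalis formosensis	nad6	0	0
Haemaphysalis formosensis	rrnL	0
Haemaphysalis formosensis	rrnS	0
Haemaphysalis formosensis	tRNAs	0
Haemaphysalis parva	atp8-atp6	2	1
Haemaphysalis parva	cytb	1	1
Haemaphysalis parva	cox1	0	0
Haemaphysalis parva	cox2	0	0
Haemaphysalis parva	cox3	0	0
Haemaphysalis parva	nad1	2	2
Haemaphysalis parva	nad2	0	0
Haemaphysalis parva	nad3	0	0
Haemaphysalis parva	nad4	0	0
Haemaphysalis parva	nad4L	0	0
Haemaphysalis parva	nad5	0	0
Haemaphysalis parva	nad6	0	0
Haemaphysalis parva	rrnL	0
Haemaphysalis parva	rrnS	0
Haemaphysalis parva	tRNAs	1
Rhipicephalus microplus	atp8-atp6	2	1
Rhipicephalus microplus	cytb	3	0
Rhipicephalus microplus	cox1	6	0
Rhipicephalus microplus	cox2	2	0
Rhipicephalus microplus	cox3	3	0
Rhipicephalus microplus	nad1	3	0
Rhipicephalus microplus	nad2	2	0
Rhipicephalus microplus	nad3	0	0
Rhipicephalus microplus	nad4	6	2
Rhipicephalus microplus	nad4L	1	0
Rhipicephalus microplus	nad5	6	0
Rhipicephalus microplus	nad6	0	0
Rhipicephalus microplus	rrnL	0
Rhipicephalus microplus	rrnS	0
Rhipicephalus microplus	tRNAs	6
Amblyomma cajennense	atp8-atp6	13	4
Amblyomma cajennense	cytb	11	10
Amblyomma cajennense	cox1	22	0
Amblyomma cajennense	cox2	8	0
Amblyomma cajennense	cox3	7	3
Amblyomma cajennense	nad1	13	1
Amblyomma cajennense	nad2	6	3
Amblyomma cajennense	nad3	6	1
Amblyomma cajennense	nad4	19	1
Amblyomma cajennense	nad4L	3	0
Amblyomma cajennense	nad5	27	10
Amblyomma cajennense	nad6	1	0
Amblyomma cajennense	rrnL	15
Amblyomma cajennense	rrnS	7
Amblyomma cajennense	tRNAs	8
Argas sp.	atp8-atp6	1	0
Argas sp.	cytb	0	0
Argas sp.	cox1	2	0
Argas sp.	cox2	0	0
Argas sp.	cox3	1	0
Argas sp.	nad1	0	0
Argas sp.	nad2	0	0
Argas sp.	nad3	0	0
Argas sp.	nad4	3	0
Argas sp.	nad4L	0	0
Argas sp.	nad5	3	0
Argas sp.	nad6	0	0
Argas sp.	rrnL	0
Argas sp.	rrnS	1
Argas sp.	tRNAs	0
Rhipicephalus geigyi	atp8-atp6	0	0
Rhipicephalus geigyi	cytb	0	0
Rhipicephalus geigyi	cox1	1	0
Rhipicephalus geigyi	cox2	0	0
Rhipicephalus geigyi	cox3	0	0
Rhipicephalus geigyi	nad1	0	0
Rhipicephalus geigyi	nad2	1	1
Rhipicephalus geigyi	nad3	0	0
Rhipicephalus geigyi	nad4	5	4
Rhipicephalus geigyi	nad4L	0	0
Rhipicephalus geigyi	nad5	0	0
Rhipicephalus geigyi	nad6	0	0
Rhipicephalus geigyi	rrnL	0
Rhipicephalus geigyi	rrnS	0
Rhipicephalus geigyi	tRNAs	1
Otobius megnini	atp8-atp6	5	5
Otobius megnini	cytb	1	1
Otobius megnini	cox1	6	0
Otobius megnini	cox2	0	0
Otobius megnini	cox3	1	0
Otobius megnini	nad1	3	3
Otobius megnini	nad2	3	3
Otobius megnini	nad3	5	5
Otobius megnini	nad4	0	0
Otobius megnini	nad4L	0	0
Otobius megnini	nad5	0	0
Otobius megnini	nad6	0	0
Otobius megnini	rrnL	0
Otobius megnini	rrnS	1
Otobius megnini	tRNAs	0
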