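accession	protein_name	score	coverage_percent	mass_da	pai	t_cell_inductor	b_cell_inductor
P02662	alpha-S1-casein (Bos d 9)	32934	43	24570	195.07	25	12
P02754	beta-lactoglobulin (Bos d 5)	18489	33	20269	186.95	21	7
P02666	beta-casein (Bos d 11)	3930	33	25148	4.25	25	13
P00711	alpha-lactalbumin (Bos d 4)	1387	26	16236	4.99	18	6
P02663	alpha-S2-casein (Bos d 10)	688	19	26173	1.61	26	12
P31096	Osteopontin	393	33	31000	1.95	31	8
P18892	Butyrophilin subfamily 1	171	5	59923	0.15	57	22
P80195	Glycosylation-dependent cell adhesion molecule	81	23	17198	1.05	21	6
Q5GN72	alpha-1-glycoprotein (Bos d 2)	74	5	23158	0.11	40	15
P04258	Collagen alpha-1 (III) chain	71	1	93708	0.05	109	3
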