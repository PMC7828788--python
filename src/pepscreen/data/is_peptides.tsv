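protein_id	allergen_label	start	end	sequence	source	flag
P00711	Bos d 4	56	68	DTQAIVQNNDSTE	IS	
P00711	Bos d 4	88	98	SSNICNISCDK	IS	
P02754	Bos d 5	124	132	ENSAEPEQS	IS	
P02769	Bos d 6	189	197	QECCQAEDK	IS	
P02769	Bos d 6	287	297	ICDNQDTISSK	IS	
P02769	Bos d 6	319	328	DAIPENLPPL	IS	
P02769	Bos d 6	438	446	VPQVSTPTL	IS	
P02769	Bos d 6	460	468	CCTKPESER	IS	
P02662	Bos d 9	58	69	DIGSESTEDQAM	IS	
P02662	Bos d 9	76	94	EAESISSSEEIVPNSVEQK	IS	
P02662	Bos d 9	125	134	EIVPNSAEER	IS	
P02662	Bos d 9	195	208	SDIPNPIGSENSEK	IS	
P02663	Bos d 10	22	34	VSSSEESIISQET	IS	
P02663	Bos d 10	68	85	SIGSSSEESAEVATEEVK	IS	
P02663	Bos d 10	130	138	NAVPITPTL	IS	
P02666	Bos d 11	22	30	NVPGEIVES	IS	
P02666	Bos d 11	32	40	SSSEESITR	IS	
P02666	Bos d 11	49	59	QSEEQQQTEDE	IS	
P02666	Bos d 11	76	85	PFPGPIPNSL	IS	
P02666	Bos d 11	93	102	TQTPVVVPPF	IS	
P02668	Bos d 12	20	31	GAQEQNQEQPIR	IS	
P02668	Bos d 12	108	116	SCQAQPTTM	IS	
P02668	Bos d 12	138	166	TEIPTINTIASGEPTSTPTTEAVESTVAT	IS	
P02668	Bos d 12	168	190	EDSPEVIESPPEINTVQVTSTAV	IS	
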