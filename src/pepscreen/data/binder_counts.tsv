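peptide_id	protein_id	source	weak_drb1	weak_dq	weak_dp	strong_drb1	strong_dq	strong_dp
DTQAIVQNNDSTE	P00711	IS	7	1	5	1	4	2
SSNICNISCDK	P00711	IS	0	1	0	0	4	0
ENSAEPEQS	P02754	IS	0	5	3	0	0	0
QECCQAEDK	P02769	IS	0	3	0	0	0	0
ICDNQDTISSK	P02769	IS	2	3	3	9	2	3
DAIPENLPPL	P02769	IS	0	0	0	0	5	7
VPQVSTPTL	P02769	IS	6	0	3	3	5	4
CCTKPESER	P02769	IS	0	4	1	0	1	0
DIGSESTEDQAM	P02662	IS	6	0	5	2	5	1
EAESISSSEEIVPNSVEQK	P02662	IS	0	0	1	8	5	6
EIVPNSAEER	P02662	IS	3	0	6	2	5	1
SDIPNPIGSENSEK	P02662	IS	8	0	6	0	5	1
VSSSEESIISQET	P02663	IS	2	0	2	1	5	5
SIGSSSEESAEVATEEVK	P02663	IS	5	0	4	3	5	3
NAVPITPTL	P02663	IS	0	1	1	0	4	0
NVPGEIVES	P02666	IS	0	3	1	0	2	0
SSSEESITR	P02666	IS	0	1	1	0	0	0
QSEEQQQTEDE	P02666	IS	0	5	1	0	0	0
PFPGPIPNSL	P02666	IS	6	1	0	3	4	7
TQTPVVVPPF	P02666	IS	0	0	7	0	5	0
GAQEQNQEQPIR	P02668	IS	0	0	5	0	5	2
SCQAQPTTM	P02668	IS	0	0	7	0	5	0
TEIPTINTIASGEPTSTPTTEAVESTVAT	P02668	IS	1	0	0	8	5	7
EDSPEVIESPPEINTVQVTSTAV	P02668	IS	4	0	0	7	5	7
NNKIWCKDDQNPHSSNICNISCDK	P00711	IV	1	1	4	7	4	3
LVRTPEVDDEALEKFDKALKALPM	P02754	IV	3	0	0	9	5	7
GYLEQLLRLKKYKVPQLEIVPNSA	P02662	IV	0	0	0	12	5	7
SMKEGIHAQQKEPMIGVNQELAYF	P02662	IV	3	0	0	8	5	7
SDIPNPIGSENSEK	P02662	IV	8	0	6	0	5	1
QKHIQKEDVPSERYLGYLEQLLRL	P02662	IV	1	0	0	8	5	7
GPVGNPGPAGPAGPRGEVGLPGLS	P04258	IV	6	0	4	2	5	3
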