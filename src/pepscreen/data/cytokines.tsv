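peptide_id	source	cytokine	n_inducing	score_min	score_max	window_length
DTQAIVQNNDSTE	IS	IL4	0			9
DTQAIVQNNDSTE	IS	IFNG	2	0.33	0.39	9
SSNICNISCDK	IS	IL4	4	0.99	1.58	9
SSNICNISCDK	IS	IFNG	0			9
ENSAEPEQS	IS	IL4	2	1.15	2.04	9
ENSAEPEQS	IS	IFNG	0			9
ICDNQDTISSK	IS	IL4	3	0.52	1.05	9
ICDNQDTISSK	IS	IFNG	3	0.34	0.39	9
DIGSESTEDQAM	IS	IL4	2	0.21	0.38	9
DIGSESTEDQAM	IS	IFNG	0			9
EAESISSSEEIVPNSVEQK	IS	IL4	2	0.25	0.99	9
EAESISSSEEIVPNSVEQK	IS	IFNG	1	0.75	0.75	9
SDIPNPIGSENSEK	IS	IL4	7	0.56	1.66	9
SDIPNPIGSENSEK	IS	IFNG	2	0.07	0.35	9
VSSSEESIISQET	IS	IL4	1	0.26	0.26	9
VSSSEESIISQET	IS	IFNG	2	0.01	0.39	9
SIGSSSEESAEVATEEVK	IS	IL4	5	1.12	1.92	9
SIGSSSEESAEVATEEVK	IS	IFNG	8	0.05	0.72	9
QSEEQQQTEDE	IS	IL4	0			9
QSEEQQQTEDE	IS	IFNG	0			9
GAQEQNQEQPIR	IS	IL4	4	0.47	0.8	9
GAQEQNQEQPIR	IS	IFNG	0			9
TEIPTINTIASGEPTSTPTTEAVESTVAT	IS	IL4	14	0.29	1.14	9
TEIPTINTIASGEPTSTPTTEAVESTVAT	IS	IFNG	5	0.11	0.31	9
EDSPEVIESPPEINTVQVTSTAV	IS	IL4	0			9
EDSPEVIESPPEINTVQVTSTAV	IS	IFNG	0			9
NNKIWCKDDQNPHSSNICNISCDK	IV	IL4	1	0.27	0.27	9
NNKIWCKDDQNPHSSNICNISCDK	IV	IFNG	0			9
LVRTPEVDDEALEKFDKALKALPM	IV	IL4	0			9
LVRTPEVDDEALEKFDKALKALPM	IV	IFNG	5	0.11	0.31	9
GYLEQLLRLKKYKVPQLEIVPNSA	IV	IL4	1	0.89	0.89	9
GYLEQLLRLKKYKVPQLEIVPNSA	IV	IFNG	1	0.04	0.04	9
SMKEGIHAQQKEPMIGVNQELAYF	IV	IL4	2	0.32	0.47	9
SMKEGIHAQQKEPMIGVNQELAYF	IV	IFNG	0			9
SDIPNPIGSENSEK	IV	IL4	7	0.56	1.66	9
SDIPNPIGSENSEK	IV	IFNG	0			9
QKHIQKEDVPSERYLGYLEQLLRL	IV	IL4	1	0.51	0.51	9
QKHIQKEDVPSERYLGYLEQLLRL	IV	IFNG	2	0.21	0.63	9
GPVGNPGPAGPAGPRGEVGLPGLS	IV	IL4	1	0.54	0.54	9
GPVGNPGPAGPAGPRGEVGLPGLS	IV	IFNG	2	0.04	0.11	9
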