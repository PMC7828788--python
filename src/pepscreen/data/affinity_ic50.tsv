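peptide_id	protein_id	source	allele	locus	scale	value	censored
DTQAIVQNNDSTE	P00711	IS	DRB1*01:01	DRB1	ic50_nM	121.63	0
DTQAIVQNNDSTE	P00711	IS	DQ7	DQ	ic50_nM	101.36	0
DTQAIVQNNDSTE	P00711	IS	DQ8	DQ	ic50_nM	76.41	0
DTQAIVQNNDSTE	P00711	IS	DRB1*03:01	DRB1	ic50_nM	93.56	0
DTQAIVQNNDSTE	P00711	IS	DRB1*14:19	DRB1	ic50_nM	96.68	0
DTQAIVQNNDSTE	P00711	IS	DRB1*14:21	DRB1	ic50_nM	134.1	0
SSNICNISCDK	P00711	IS	DRB1*01:01	DRB1	ic50_nM	502.78	0
SSNICNISCDK	P00711	IS	DQ7	DQ	ic50_nM	308.52	0
SSNICNISCDK	P00711	IS	DQ8	DQ	ic50_nM	291.38	0
SSNICNISCDK	P00711	IS	DRB1*03:01	DRB1	ic50_nM	365.66	0
SSNICNISCDK	P00711	IS	DRB1*14:19	DRB1	ic50_nM	445.64	0
SSNICNISCDK	P00711	IS	DRB1*14:21	DRB1	ic50_nM	462.78	0
ICDNQDTISSK	P02769	IS	DRB1*01:01	DRB1	ic50_nM	462.78	0
ICDNQDTISSK	P02769	IS	DQ7	DQ	ic50_nM	514.2	0
ICDNQDTISSK	P02769	IS	DQ8	DQ	ic50_nM	354.23	0
ICDNQDTISSK	P02769	IS	DRB1*03:01	DRB1	ic50_nM	234.25	0
ICDNQDTISSK	P02769	IS	DRB1*14:19	DRB1	ic50_nM	359.94	0
ICDNQDTISSK	P02769	IS	DRB1*14:21	DRB1	ic50_nM	468.5	0
DIGSESTEDQAM	P02662	IS	DRB1*01:01	DRB1	ic50_nM	266.88	0
DIGSESTEDQAM	P02662	IS	DQ7	DQ	ic50_nM	240.19	0
DIGSESTEDQAM	P02662	IS	DQ8	DQ	ic50_nM	68.2	0
DIGSESTEDQAM	P02662	IS	DRB1*03:01	DRB1	ic50_nM	169.02	0
DIGSESTEDQAM	P02662	IS	DRB1*14:19	DRB1	ic50_nM	287.63	0
DIGSESTEDQAM	P02662	IS	DRB1*14:21	DRB1	ic50_nM	287.63	0
EAESISSSEEIVPNSVEQK	P02662	IS	DRB1*01:01	DRB1	ic50_nM	462.53	0
EAESISSSEEIVPNSVEQK	P02662	IS	DQ7	DQ	ic50_nM	107.92	0
EAESISSSEEIVPNSVEQK	P02662	IS	DQ8	DQ	ic50_nM	16.96	0
EAESISSSEEIVPNSVEQK	P02662	IS	DRB1*03:01	DRB1	ic50_nM	174.73	0
EAESISSSEEIVPNSVEQK	P02662	IS	DRB1*14:19	DRB1	ic50_nM	277.52	0
EAESISSSEEIVPNSVEQK	P02662	IS	DRB1*14:21	DRB1	ic50_nM	426.55	0
SDIPNPIGSENSEK	P02662	IS	DRB1*01:01	DRB1	ic50_nM	96.91	0
SDIPNPIGSENSEK	P02662	IS	DQ7	DQ	ic50_nM	67.84	0
SDIPNPIGSENSEK	P02662	IS	DQ8	DQ	ic50_nM	48.46	0
SDIPNPIGSENSEK	P02662	IS	DRB1*03:01	DRB1	ic50_nM	99.07	0
SDIPNPIGSENSEK	P02662	IS	DRB1*14:19	DRB1	ic50_nM	105.53	0
SDIPNPIGSENSEK	P02662	IS	DRB1*14:21	DRB1	ic50_nM	106.6	0
VSSSEESIISQET	P02663	IS	DRB1*01:01	DRB1	ic50_nM	124.75	0
VSSSEESIISQET	P02663	IS	DQ7	DQ	ic50_nM	46.78	0
VSSSEESIISQET	P02663	IS	DQ8	DQ	ic50_nM	1.72	0
VSSSEESIISQET	P02663	IS	DRB1*03:01	DRB1	ic50_nM	102.92	0
VSSSEESIISQET	P02663	IS	DRB1*14:19	DRB1	ic50_nM	145.02	0
VSSSEESIISQET	P02663	IS	DRB1*14:21	DRB1	ic50_nM	146.58	0
SIGSSSEESAEVATEEVK	P02663	IS	DRB1*01:01	DRB1	ic50_nM	272.29	0
SIGSSSEESAEVATEEVK	P02663	IS	DQ7	DQ	ic50_nM	47.35	0
SIGSSSEESAEVATEEVK	P02663	IS	DQ8	DQ	ic50_nM	0.53	0
SIGSSSEESAEVATEEVK	P02663	IS	DRB1*03:01	DRB1	ic50_nM	260.45	0
SIGSSSEESAEVATEEVK	P02663	IS	DRB1*14:19	DRB1	ic50_nM	293.01	0
SIGSSSEESAEVATEEVK	P02663	IS	DRB1*14:21	DRB1	ic50_nM	295.97	0
QSEEQQQTEDE	P02666	IS	DRB1*01:01	DRB1	ic50_nM	531.34	0
QSEEQQQTEDE	P02666	IS	DQ7	DQ	ic50_nM	508.49	0
QSEEQQQTEDE	P02666	IS	DQ8	DQ	ic50_nM	165.69	0
QSEEQQQTEDE	P02666	IS	DRB1*03:01	DRB1	ic50_nM	565.62	0
QSEEQQQTEDE	P02666	IS	DRB1*14:19	DRB1	ic50_nM	571.34	0
QSEEQQQTEDE	P02666	IS	DRB1*14:21	DRB1	ic50_nM	571.34	0
GAQEQNQEQPIR	P02668	IS	DRB1*01:01	DRB1	ic50_nM	278.74	0
GAQEQNQEQPIR	P02668	IS	DQ7	DQ	ic50_nM	281.7	0
GAQEQNQEQPIR	P02668	IS	DQ8	DQ	ic50_nM	204.61	0
GAQEQNQEQPIR	P02668	IS	DRB1*03:01	DRB1	ic50_nM	275.77	0
GAQEQNQEQPIR	P02668	IS	DRB1*14:19	DRB1	ic50_nM	278.74	0
GAQEQNQEQPIR	P02668	IS	DRB1*14:21	DRB1	ic50_nM	287.63	0
TEIPTINTIASGEPTSTPTTEAVESTVAT	P02668	IS	DRB1*01:01	DRB1	ic50_nM	5000.0	1
TEIPTINTIASGEPTSTPTTEAVESTVAT	P02668	IS	DQ7	DQ	ic50_nM	4253.87	0
TEIPTINTIASGEPTSTPTTEAVESTVAT	P02668	IS	DQ8	DQ	ic50_nM	5000.0	1
TEIPTINTIASGEPTSTPTTEAVESTVAT	P02668	IS	DRB1*03:01	DRB1	ic50_nM	5000.0	1
TEIPTINTIASGEPTSTPTTEAVESTVAT	P02668	IS	DRB1*14:19	DRB1	ic50_nM	5000.0	1
TEIPTINTIASGEPTSTPTTEAVESTVAT	P02668	IS	DRB1*14:21	DRB1	ic50_nM	5000.0	1
EDSPEVIESPPEINTVQVTSTAV	P02668	IS	DRB1*01:01	DRB1	ic50_nM	973.05	0
EDSPEVIESPPEINTVQVTSTAV	P02668	IS	DQ7	DQ	ic50_nM	858.58	0
EDSPEVIESPPEINTVQVTSTAV	P02668	IS	DQ8	DQ	ic50_nM	629.62	0
EDSPEVIESPPEINTVQVTSTAV	P02668	IS	DRB1*03:01	DRB1	ic50_nM	2146.44	0
EDSPEVIESPPEINTVQVTSTAV	P02668	IS	DRB1*14:19	DRB1	ic50_nM	2432.64	0
EDSPEVIESPPEINTVQVTSTAV	P02668	IS	DRB1*14:21	DRB1	ic50_nM	2690.21	0
NNKIWCKDDQNPHSSNICNISCDK	P00711	IV	DRB1*01:01	DRB1	ic50_nM	4244.21	0
NNKIWCKDDQNPHSSNICNISCDK	P00711	IV	DQ7	DQ	ic50_nM	3480.25	0
NNKIWCKDDQNPHSSNICNISCDK	P00711	IV	DQ8	DQ	ic50_nM	3862.23	0
NNKIWCKDDQNPHSSNICNISCDK	P00711	IV	DRB1*03:01	DRB1	ic50_nM	3352.93	0
NNKIWCKDDQNPHSSNICNISCDK	P00711	IV	DRB1*14:19	DRB1	ic50_nM	3650.02	0
NNKIWCKDDQNPHSSNICNISCDK	P00711	IV	DRB1*14:21	DRB1	ic50_nM	4116.89	0
LVRTPEVDDEALEKFDKALKALPM	P02754	IV	DRB1*01:01	DRB1	ic50_nM	1952.34	0
LVRTPEVDDEALEKFDKALKALPM	P02754	IV	DQ7	DQ	ic50_nM	3268.04	0
LVRTPEVDDEALEKFDKALKALPM	P02754	IV	DQ8	DQ	ic50_nM	1273.26	0
LVRTPEVDDEALEKFDKALKALPM	P02754	IV	DRB1*03:01	DRB1	ic50_nM	2588.97	0
LVRTPEVDDEALEKFDKALKALPM	P02754	IV	DRB1*14:19	DRB1	ic50_nM	1527.92	0
LVRTPEVDDEALEKFDKALKALPM	P02754	IV	DRB1*14:21	DRB1	ic50_nM	1315.71	0
GYLEQLLRLKKYKVPQLEIVPNSA	P02662	IV	DRB1*01:01	DRB1	ic50_nM	1145.94	0
GYLEQLLRLKKYKVPQLEIVPNSA	P02662	IV	DQ7	DQ	ic50_nM	3013.39	0
GYLEQLLRLKKYKVPQLEIVPNSA	P02662	IV	DQ8	DQ	ic50_nM	3310.49	0
GYLEQLLRLKKYKVPQLEIVPNSA	P02662	IV	DRB1*03:01	DRB1	ic50_nM	2970.95	0
GYLEQLLRLKKYKVPQLEIVPNSA	P02662	IV	DRB1*14:19	DRB1	ic50_nM	1612.8	0
GYLEQLLRLKKYKVPQLEIVPNSA	P02662	IV	DRB1*14:21	DRB1	ic50_nM	373.49	0
SMKEGIHAQQKEPMIGVNQELAYF	P02662	IV	DRB1*01:01	DRB1	ic50_nM	3437.81	0
SMKEGIHAQQKEPMIGVNQELAYF	P02662	IV	DQ7	DQ	ic50_nM	3310.49	0
SMKEGIHAQQKEPMIGVNQELAYF	P02662	IV	DQ8	DQ	ic50_nM	1230.82	0
SMKEGIHAQQKEPMIGVNQELAYF	P02662	IV	DRB1*03:01	DRB1	ic50_nM	1527.92	0
SMKEGIHAQQKEPMIGVNQELAYF	P02662	IV	DRB1*14:19	DRB1	ic50_nM	2376.76	0
SMKEGIHAQQKEPMIGVNQELAYF	P02662	IV	DRB1*14:21	DRB1	ic50_nM	1527.82	0
SDIPNPIGSENSEK	P02662	IV	DRB1*01:01	DRB1	ic50_nM	96.91	0
SDIPNPIGSENSEK	P02662	IV	DQ7	DQ	ic50_nM	67.84	0
SDIPNPIGSENSEK	P02662	IV	DQ8	DQ	ic50_nM	48.46	0
SDIPNPIGSENSEK	P02662	IV	DRB1*03:01	DRB1	ic50_nM	99.07	0
SDIPNPIGSENSEK	P02662	IV	DRB1*14:19	DRB1	ic50_nM	105.53	0
SDIPNPIGSENSEK	P02662	IV	DRB1*14:21	DRB1	ic50_nM	106.6	0
QKHIQKEDVPSERYLGYLEQLLRL	P02662	IV	DRB1*01:01	DRB1	ic50_nM	1909.9	0
QKHIQKEDVPSERYLGYLEQLLRL	P02662	IV	DQ7	DQ	ic50_nM	3055.83	0
QKHIQKEDVPSERYLGYLEQLLRL	P02662	IV	DQ8	DQ	ic50_nM	1867.45	0
QKHIQKEDVPSERYLGYLEQLLRL	P02662	IV	DRB1*03:01	DRB1	ic50_nM	2037.22	0
QKHIQKEDVPSERYLGYLEQLLRL	P02662	IV	DRB1*14:19	DRB1	ic50_nM	2970.95	0
QKHIQKEDVPSERYLGYLEQLLRL	P02662	IV	DRB1*14:21	DRB1	ic50_nM	2291.87	0
GPVGNPGPAGPAGPRGEVGLPGLS	P04258	IV	DRB1*01:01	DRB1	ic50_nM	2776.07	0
GPVGNPGPAGPAGPRGEVGLPGLS	P04258	IV	DQ7	DQ	ic50_nM	343.43	0
GPVGNPGPAGPAGPRGEVGLPGLS	P04258	IV	DQ8	DQ	ic50_nM	2747.45	0
GPVGNPGPAGPAGPRGEVGLPGLS	P04258	IV	DRB1*03:01	DRB1	ic50_nM	2833.31	0
GPVGNPGPAGPAGPRGEVGLPGLS	P04258	IV	DRB1*14:19	DRB1	ic50_nM	2861.93	0
GPVGNPGPAGPAGPRGEVGLPGLS	P04258	IV	DRB1*14:21	DRB1	ic50_nM	2861.93	0
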