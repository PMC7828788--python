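protein_id	kind	start	end	sequence	citation
P00711	Tcell	58	75	QAIVQNNDSTEYGLFQIN	B27
P00711	Tcell	74	91	INNKIWCKDDQNPHSSNI	B27
P00711	IgE	36	77	GYGGVSLPEWVCTTFHTSGYDTQAIVQNNDSTEYGLFQINNK	B28
P00711	IgE	79	98		B29
P02754	Tcell	113	133	TDYKKYLLFCMENSAEPEQSL	B23,B24
P02769	Tcell	317	336		B32
P02662	Tcell	58	81	DIGSESTEDQAMEDIKQMEAESIS	B33
P02662	Tcell	88	111	PNSVEQKHIQKEDVPSERYLGYLE	B33
P02662	Tcell	106	129		B33
P02662	IgE	54	63	ELSKDIGSES	B10,B34
P02662	IgE	64	78	TEDQAMEDIKQMEAE	B10,B34
P02662	IgE	84	93	EEIVPNSVEQ	B10
P02662	IgE	124	135	LEIVPNSAEERL	B10
P02662	IgE	188	207	YTDAPSFSDIPNPIGSENSE	B10,B34
P02662	IgE	190	209	DAPSFSDIPNPIGSENSEKT	B10,B34
P02662	IgE	194	213	FSDIPNPIGSENSEKTTMPL	B10,B34
P02663	IgE	16	34	KNTMEHVSSSEESIISQETY	B35,B36
P02663	IgE	28	47		B35,B36
P02663	IgE	57	71	EVVRNANEEEYSIGS	B34,B35
P02663	IgE	82	101	EEVKITVDDKHYQKALNEIN	B34,B35
P02663	Tcell	73	84	SEESAEVATEEV	B37
P02663	IgE	132	143	VPITPTLNREQL	B36
P02666	IgE	16	31	RELEELNVPGEIVESL	B10
P02666	IgE	31	50	LSSSEESITRINKKIEKFQS	B34
P02666	IgE	49	65	QSEEQQQTEDELQDKIH	B35
P02666	IgE	70	85	TQSLVYPFPGPIPNSL	B10
P02666	IgE	98	107	VVPPFLQPEV	B10
P02668	IgE	132	147	KKNQDKTEIPTINTIA	B10
P02668	IgE	158	169	EAVESTVATLED	B10
P02668	IgE	170	189	SPEVIESPPEINTVQVTSTA	B10
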