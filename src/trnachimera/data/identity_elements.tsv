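isoacceptor	gene_id	position	base
Trp	EcTrp1	1	A
Trp	EcTrp1	2	G
Trp	EcTrp1	3	G
Trp	EcTrp1	70	C
Trp	EcTrp1	71	C
Trp	EcTrp1	72	T
Trp	EcTrp1	73	G
Ala	EcAla1	2	G
Ala	EcAla1	3	G
Ala	EcAla1	4	G
Ala	EcAla1	20	G
Ala	EcAla1	69	C
Ala	EcAla1	70	T
Ala	EcAla1	71	C
Ala	EcAla1	73	A
Ala	EcAla2	2	G
Ala	EcAla2	3	G
Ala	EcAla2	4	G
Ala	EcAla2	20	G
Ala	EcAla2	69	C
Ala	EcAla2	70	T
Ala	EcAla2	71	C
Ala	EcAla2	73	A
Arg	EcArg1	20	A
Arg	EcArg1	73	G
Arg	EcArg2	20	A
Arg	EcArg2	73	G
Phe	EcPhe1	20	T
Phe	EcPhe1	59	T
Phe	EcPhe1	60	T
Leu	EcLeu1	14	A
Leu	EcLeu1	15	G
Leu	EcLeu1	16	C
Leu	EcLeu1	73	A
Cys	EcCys1	15	G
Cys	EcCys1	73	T
Pro	EcPro1	15	G
Pro	EcPro1	73	A
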