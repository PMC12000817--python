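Start	End	Length (bp)	Direction	Type	Gene name	Gene product	Anti-codon	Start codon	Stop codon
1	987	987	+	control region	-	-	-	-	-
988	1058	71	+	tRNA	trnE	tRNA-Glu	TTC	-	-
1059	1577	519	+	CDS	ND6	NADH dehydrogenase subunit 6	-	ATG	TAG
1599	1668	70	+	tRNA	trnP	tRNA-Pro	TGG	-	-
1669	2863	1195	+	control region	-	-	-	-	-
2931	2864	68	-	tRNA	trnT	tRNA-Thr	TGT	-	-
4076	2934	1143	-	CDS	CYTB	cytochrome b	-	ATG	TAA
5903	4089	1815	-	CDS	ND5	NADH dehydrogenase subunit 5	-	ATG	TAA
5974	5904	71	-	tRNA	trnL	tRNA-Leu	TAG	-	-
6039	5975	65	-	tRNA	trnS	tRNA-Ser	GCT	-	-
6110	6041	70	-	tRNA	trnH	tRNA-His	GTG	-	-
7488	6106	1383	-	CDS	ND4	NADH dehydrogenase subunit 4	-	ATG	AGG
7778	7482	297	-	CDS	ND4L	NADH dehydrogenase subunit 4L	-	ATG	TAA
7848	7780	69	-	tRNA	trnR	tRNA-Arg	TCG	-	-
8204	7854	354	-	CDS	ND3	NADH dehydrogenase subunit 3	-	ATG	AGG
8273	8205	69	-	tRNA	trnG	tRNA-Gly	TCC	-	-
9057	8274	784	-	CDS	COX3	cytochrome c oxidase subunit III	-	ATG	CCT
9740	9057	684	-	CDS	ATP6	ATP synthase F0 subunit 6	-	ATG	TAA
9898	9731	168	-	CDS	ATP8	ATP synthase F0 subunit 8	-	ATG	TAA
9970	9900	71	-	tRNA	trnK	tRNA-Lys	TTT	-	-
10655	9972	684	-	CDS	COX2	cytochrome c oxidase subunit II	-	ATG	TAA
10726	10658	69	-	tRNA	trnD	tRNA-Asp	GTC	-	-
10731	10802	72	+	tRNA	trnS	tRNA-Ser	TGA	-	-
12344	10794	1551	-	CDS	COX1	cytochrome c oxidase subunit I	-	GTG	AGG
12346	12415	70	+	tRNA	trnY	tRNA-Tyr	GTA	-	-
12416	12482	67	+	tRNA	trnC	tRNA-Cys	GCA	-	-
12485	12557	73	+	tRNA	trnN	tRNA-Asn	GTT	-	-
12560	12628	69	+	tRNA	trnA	tRNA-Ala	TGC	-	-
12702	12630	73	-	tRNA	trnW	tRNA-Trp	TCA	-	-
13747	12701	1047	-	CDS	ND2	NADH dehydrogenase subunit 2	-	ATG	TAG
13816	13748	69	-	tRNA	trnM	tRNA-Met	CAT	-	-
13816	13886	71	+	tRNA	trnQ	tRNA-Gln	TTG	-	-
13971	13900	72	-	tRNA	trnI	tRNA-Ile	GAU	-	-
14947	13970	978	-	CDS	ND1	NADH dehydrogenase subunit 1	-	ATG	AGG
15030	14957	74	-	tRNA	trnL	tRNA-Leu	TAA	-	-
16634	15030	1605	-	rRNA	l-rRNA	16S ribosomal RNA	-	-	-
16706	16635	72	-	tRNA	trnV	tRNA-Val	TAC	-	-
17681	16706	976	-	rRNA	s-rRNA	12S ribosomal RNA	-	-	-
17750	17681	70	-	tRNA	trnF	tRNA-Phe	GAA	-	-
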