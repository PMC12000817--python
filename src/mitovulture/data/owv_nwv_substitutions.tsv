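gene	position	residue_owv	residue_nwv	class_owv	class_nwv
ATP8	7	A	N	Hydrophobic	Polar uncharged
ATP8	30	P	S	Special case	Polar uncharged
COX1	1	G	A	Special case	Hydrophobic
COX1	3	S	F	Polar uncharged	Hydrophobic
COX2	4	H	N	Positive	Polar uncharged
COX2	43	A	T	Hydrophobic	Polar uncharged
COX2	90	N	D	Polar uncharged	Negative
COX2	156	N	G	Polar uncharged	Special case
COX2	161	A	S	Hydrophobic	Polar uncharged
COX2	166	A	T	Hydrophobic	Polar uncharged
COX3	152	M	T	Hydrophobic	Polar uncharged
COX3	224	N	K	Polar uncharged	Positive
CYTB	5	P	I	Special case	Hydrophobic
CYTB	376	M	T	Hydrophobic	Polar uncharged
CYTB	378	C	Y	Special case	Hydrophobic
CYTB	381	T	K	Polar uncharged	Positive
ND1	9	H	Y	Positive	Hydrophobic
ND1	79	T	I	Polar uncharged	Hydrophobic
ND1	81	M	T	Hydrophobic	Polar uncharged
ND1	160	V	T	Hydrophobic	Polar uncharged
ND1	171	A	T	Hydrophobic	Polar uncharged
ND1	173	T	A	Polar uncharged	Hydrophobic
ND1	189	T	A	Polar uncharged	Hydrophobic
ND1	260	Q	E	Polar uncharged	Negative
ND1	263	T	P	Polar uncharged	Special case
ND1	312	I	T	Hydrophobic	Polar uncharged
ND1	323	C	Y	Special case	Hydrophobic
ND2	5	T	A	Polar uncharged	Hydrophobic
ND2	56	T	A	Polar uncharged	Hydrophobic
ND2	65	T	A	Polar uncharged	Hydrophobic
ND2	140	V	T	Hydrophobic	Polar uncharged
ND2	185	A	S	Hydrophobic	Polar uncharged
ND2	229	T	M	Polar uncharged	Hydrophobic
ND2	299	H	Y	Positive	Hydrophobic
ND3	7	T	M	Polar uncharged	Hydrophobic
ND3	19	I	T	Hydrophobic	Polar uncharged
ND3	64	L	P	Hydrophobic	Special case
ND3	77	T	P	Polar uncharged	Special case
ND4	8	T	M	Polar uncharged	Hydrophobic
ND4	40	H	Q	Positive	Polar uncharged
ND4	57	C	G	Special case	Special case
ND4	63	S	A	Polar uncharged	Hydrophobic
ND4	112	A	T	Hydrophobic	Polar uncharged
ND4	170	H	Q	Positive	Polar uncharged
ND4	171	I	T	Hydrophobic	Polar uncharged
ND4	195	L	S	Hydrophobic	Polar uncharged
ND4	201	M	T	Hydrophobic	Polar uncharged
ND4L	11	S	A	Polar uncharged	Hydrophobic
ND4L	16	C	S	Special case	Polar uncharged
ND4L	43	T	A	Polar uncharged	Hydrophobic
ND5	16	A	T	Hydrophobic	Polar uncharged
ND5	61	S	M	Polar uncharged	Hydrophobic
ND5	71	I	T	Hydrophobic	Polar uncharged
ND5	332	T	M	Polar uncharged	Hydrophobic
ND5	350	A	N	Hydrophobic	Polar uncharged
ND5	382	M	T	Hydrophobic	Polar uncharged
ND5	407	A	T	Hydrophobic	Polar uncharged
ND5	438	M	T	Hydrophobic	Polar uncharged
ND5	597	T	I	Polar uncharged	Hydrophobic
ND6	36	G	A	Special case	Hydrophobic
ND6	50	P	S	Special case	Polar uncharged
ND6	53	A	S	Hydrophobic	Polar uncharged
ND6	73	C	S	Special case	Polar uncharged
ND6	78	L	P	Hydrophobic	Special case
ND6	107	E	G	Negative	Special case
ND6	126	V	S	Hydrophobic	Polar uncharged
ND6	140	W	R	Hydrophobic	Positive
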