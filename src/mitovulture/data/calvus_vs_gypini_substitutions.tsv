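gene	position	residue_group	residue_focal	class_group	class_focal
ATP6	31	F	I	Hydrophobic	Hydrophobic
ATP6	83	I	I	Hydrophobic	Hydrophobic
ATP6	139	I	I	Hydrophobic	Hydrophobic
ATP8	24	I	I	Hydrophobic	Hydrophobic
ATP8	50	S	P	Polar uncharged	Special case
COX1	468	M	M	Hydrophobic	Hydrophobic
COX2	70	I	I	Hydrophobic	Hydrophobic
CYTB	15	I	I	Hydrophobic	Hydrophobic
CYTB	26	P	S	Special case	Polar uncharged
CYTB	47	L	L	Hydrophobic	Hydrophobic
CYTB	213	I	V	Hydrophobic	Hydrophobic
CYTB	220	P	P	Special case	Special case
CYTB	307	F	F	Hydrophobic	Hydrophobic
CYTB	310	K	K	Positive	Positive
CYTB	321	L	L	Hydrophobic	Hydrophobic
CYTB	370	T	L	Polar uncharged	Hydrophobic
ND1	15	S	S	Polar uncharged	Polar uncharged
ND1	179	L	L	Hydrophobic	Hydrophobic
ND2	19	I	I	Hydrophobic	Hydrophobic
ND2	22	S	S	Polar uncharged	Polar uncharged
ND2	122	S	S	Polar uncharged	Polar uncharged
ND2	325	T	T	Polar uncharged	Polar uncharged
ND2	327	I	T	Hydrophobic	Polar uncharged
ND2	335	I	L	Hydrophobic	Hydrophobic
ND3	1	I	I	Hydrophobic	Hydrophobic
ND3	108	T	N	Hydrophobic	Polar uncharged
ND4	43	L	L	Hydrophobic	Hydrophobic
ND4	90	A	T	Hydrophobic	Polar uncharged
ND4	183	H	P	Positive	Special case
ND4	263	T	T	Polar uncharged	Polar uncharged
ND4	357	T	T	Polar uncharged	Polar uncharged
ND4	394	I	I	Hydrophobic	Hydrophobic
ND4	418	T	T	Polar uncharged	Polar uncharged
ND4L	73	T	T	Polar uncharged	Polar uncharged
ND5	30	T	T	Polar uncharged	Polar uncharged
ND5	74	M	T	Hydrophobic	Polar uncharged
ND5	291	T	T	Polar uncharged	Polar uncharged
ND5	404	Y	Y	Hydrophobic	Hydrophobic
ND5	434	E	G	Negative	Special case
ND5	600	I	I	Hydrophobic	Hydrophobic
ND6	3	A	T	Hydrophobic	Polar uncharged
ND6	142	A	A	Hydrophobic	Hydrophobic
ND6	166	M	L	Hydrophobic	Hydrophobic
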