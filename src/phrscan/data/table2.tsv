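# Key ligand-proximal residues of the Synechococcus elongatus PCC 6301 (SEL)
# photolyase and the corresponding residues in haloarchaeal Phr2 proteins.
# Positions use SEL numbering (initiator Met excluded). The interaction label
# is the ligand class each position is proximal to in the SEL crystal
# structure (DNA duplex with CPD analog, FAD catalytic cofactor, or HDF
# antenna chromophore). Note: position 282 is labelled DNA here, although it
# is also discussed as FAD-interacting; the printed label is kept.
# BOL4-2 and GSL-19 residues are identical to NRC-1 at all listed positions.
position	interaction	SEL	NRC-1	BOL4-2	GSL-19	JOR-1	Hla	BOL3-1	BOL5-1	BOL6-1
50	HDF	R	R	R	R	R	R	R	V	R
139	DNA	S	T	T	T	T	T	T	T	P
144	DNA	P	P	P	P	P	P	P	H	H
147	DNA	V	V	V	V	V	V	V	D	V
148	DNA	Y	Y	Y	Y	Y	Y	Y	F	F
149	DNA	G	T	T	T	T	S	T	S	S
150	DNA	P	Y	Y	Y	Y	Y	Y	D	Y
242	FAD	L	L	L	L	V	M	L	L	L
279	FAD	W	F	F	F	F	Y	F	F	F
282	DNA	E	Q	Q	Q	Q	Q	Q	R	Q
384	FAD	A	N	N	N	N	N	N	H	N
385	FAD	N	D	D	D	D	D	N	A	D
398	DNA	D	D	D	D	D	D	D	N	D
413	DNA	K	R	R	R	D	R	R	T	E
460	DNA	Q	R	R	R	R	R	R	H	R
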