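# Key-position residues of hT2R10, hT2R46, and selected reconstructed common
# ancestors, transcribed from the published key-residue matrix.  Tied
# ancestral predictions (alternatives reported with similar confidence across
# ingroup/outgroup samplings) are written "X/Y" with the primary call first;
# position 7.42 carried such sampling variability in the hT2R46-clade
# ancestors N34, N24 and N23.
bw_label	hT2R10	N94	N93	N83	N82	N81	N80	hT2R46	N35-37	N34	N33	N32	N25	N24	N23	N2
2.61	G	G	G	G	G	G	G	W	W	W	W	W	W	W	W	G
2.65	I	I	I	I	I	I	I	E	E	E	V	V	V	V	V	V
2.66	F	F	F	F	F	F	F	L	L	L	L	L	L	L	L	F
3.25	I	I	I	I	I	I	I	I	I	I	T	T	I	I	I	I
3.29	S	S	S	S	S	S	S	Y	Y	Y	Y	Y	Y	Y	Y	S
3.32	W	W	W	W	W	W	W	W	W	W	W	W	W	W	W	W
3.33	V	V	V	V	V	V	V	A	A	A	V	A	A	A	A	T
3.36	N	N	N	N	N	N	N	N	N	N	N	N	N	N	N	N
3.37	Q	Q	Q	Q	Q	Q	H	H	H	H	H	H	H	H	H	H
4.65	I	I	I	I	I	I	I	N	N	N	N	N	N	N	N	D
ECL2	D	N	N	N	N	S	S	N	N	N	N	N	N	N	N	N
5.39	K	K	K	K	K	N	N	N	N	N	N	N	N	N	N	N
5.40	Q	Q	Q	Q	Q	Q	Q	T	T	T	M	M	M	M	M	M
5.42	L	L	L	L	L	L	L	V	V	V	V	V	V	V	V	L
5.43	L	L	L	L	L	L	L	T	T	T	T	T	T	T	T	L
6.51	Y	Y	Y	Y	Y	Y	Y	Y	Y	Y	Y	Y	Y	Y	Y	Y
6.63	T	T	T	T	T	T	T	E	E	E	E	E	E	E	E	N
7.39	M	M	M	M	M	M	M	E	E	E	Q	Q	Q	Q	Q	M
7.42	T	T	T	T	T	T	T	A	T	T/A	I	I	I	A/T	R/A	A
7.43	A	V	V	V	V	V	V	F	F	F	F	F	F	F	I	I
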