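# zfcoscan bundled C2H2 recognition-code table.
# Simplified residue->base preference code applied identically at helix
# contact positions -1, 2, 3 and 6, in the spirit of published empirical
# C2H2 recognition codes: Arg/His->G, Asn/Gln/Thr->A, Glu/Asp->C,
# Lys/Ser->T, Gly->A/G equally; all other residues uninformative (uniform).
# position	residue	pA	pC	pG	pT
-1	A	0.2500	0.2500	0.2500	0.2500
-1	C	0.2500	0.2500	0.2500	0.2500
-1	D	0.0500	0.8500	0.0500	0.0500
-1	E	0.0500	0.8500	0.0500	0.0500
-1	F	0.2500	0.2500	0.2500	0.2500
-1	G	0.5000	0.0000	0.5000	0.0000
-1	H	0.0500	0.0500	0.8500	0.0500
-1	I	0.2500	0.2500	0.2500	0.2500
-1	K	0.0500	0.0500	0.0500	0.8500
-1	L	0.2500	0.2500	0.2500	0.2500
-1	M	0.2500	0.2500	0.2500	0.2500
-1	N	0.8500	0.0500	0.0500	0.0500
-1	P	0.2500	0.2500	0.2500	0.2500
-1	Q	0.8500	0.0500	0.0500	0.0500
-1	R	0.0500	0.0500	0.8500	0.0500
-1	S	0.0500	0.0500	0.0500	0.8500
-1	T	0.8500	0.0500	0.0500	0.0500
-1	V	0.2500	0.2500	0.2500	0.2500
-1	W	0.2500	0.2500	0.2500	0.2500
-1	Y	0.2500	0.2500	0.2500	0.2500
2	A	0.2500	0.2500	0.2500	0.2500
2	C	0.2500	0.2500	0.2500	0.2500
2	D	0.0500	0.8500	0.0500	0.0500
2	E	0.0500	0.8500	0.0500	0.0500
2	F	0.2500	0.2500	0.2500	0.2500
2	G	0.5000	0.0000	0.5000	0.0000
2	H	0.0500	0.0500	0.8500	0.0500
2	I	0.2500	0.2500	0.2500	0.2500
2	K	0.0500	0.0500	0.0500	0.8500
2	L	0.2500	0.2500	0.2500	0.2500
2	M	0.2500	0.2500	0.2500	0.2500
2	N	0.8500	0.0500	0.0500	0.0500
2	P	0.2500	0.2500	0.2500	0.2500
2	Q	0.8500	0.0500	0.0500	0.0500
2	R	0.0500	0.0500	0.8500	0.0500
2	S	0.0500	0.0500	0.0500	0.8500
2	T	0.8500	0.0500	0.0500	0.0500
2	V	0.2500	0.2500	0.2500	0.2500
2	W	0.2500	0.2500	0.2500	0.2500
2	Y	0.2500	0.2500	0.2500	0.2500
3	A	0.2500	0.2500	0.2500	0.2500
3	C	0.2500	0.2500	0.2500	0.2500
3	D	0.0500	0.8500	0.0500	0.0500
3	E	0.0500	0.8500	0.0500	0.0500
3	F	0.2500	0.2500	0.2500	0.2500
3	G	0.5000	0.0000	0.5000	0.0000
3	H	0.0500	0.0500	0.8500	0.0500
3	I	0.2500	0.2500	0.2500	0.2500
3	K	0.0500	0.0500	0.0500	0.8500
3	L	0.2500	0.2500	0.2500	0.2500
3	M	0.2500	0.2500	0.2500	0.2500
3	N	0.8500	0.0500	0.0500	0.0500
3	P	0.2500	0.2500	0.2500	0.2500
3	Q	0.8500	0.0500	0.0500	0.0500
3	R	0.0500	0.0500	0.8500	0.0500
3	S	0.0500	0.0500	0.0500	0.8500
3	T	0.8500	0.0500	0.0500	0.0500
3	V	0.2500	0.2500	0.2500	0.2500
3	W	0.2500	0.2500	0.2500	0.2500
3	Y	0.2500	0.2500	0.2500	0.2500
6	A	0.2500	0.2500	0.2500	0.2500
6	C	0.2500	0.2500	0.2500	0.2500
6	D	0.0500	0.8500	0.0500	0.0500
6	E	0.0500	0.8500	0.0500	0.0500
6	F	0.2500	0.2500	0.2500	0.2500
6	G	0.5000	0.0000	0.5000	0.0000
6	H	0.0500	0.0500	0.8500	0.0500
6	I	0.2500	0.2500	0.2500	0.2500
6	K	0.0500	0.0500	0.0500	0.8500
6	L	0.2500	0.2500	0.2500	0.2500
6	M	0.2500	0.2500	0.2500	0.2500
6	N	0.8500	0.0500	0.0500	0.0500
6	P	0.2500	0.2500	0.2500	0.2500
6	Q	0.8500	0.0500	0.0500	0.0500
6	R	0.0500	0.0500	0.8500	0.0500
6	S	0.0500	0.0500	0.0500	0.8500
6	T	0.8500	0.0500	0.0500	0.0500
6	V	0.2500	0.2500	0.2500	0.2500
6	W	0.2500	0.2500	0.2500	0.2500
6	Y	0.2500	0.2500	0.2500	0.2500
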