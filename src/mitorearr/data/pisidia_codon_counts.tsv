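codon	aa	count	rscu_printed
UUU	F	407	1.527
UUC	F	126	0.473
CUA	L	9	0.308
CUC	L	29	0.991
CUG	L	4	0.137
CUU	L	75	2.564
UUA	L	31	1.344
UUG	L	64	0.656
AUU	I	255	2.029
AUC	I	57	0.454
AUA	I	65	0.517
AUG	M	41	1
GUU	V	71	2.185
GUC	V	13	0.4
GUA	V	29	0.892
GUG	V	17	0.523
UCU	S	98	1.549
UCC	S	47	0.743
UCA	S	88	1.391
UCG	S	20	0.316
CCU	P	30	1.463
CCC	P	13	0.634
CCA	P	35	1.707
CCG	P	4	0.195
ACU	T	55	1.467
ACC	T	37	0.987
ACA	T	45	1.2
ACG	T	13	0.347
GCU	A	34	2
GCC	A	9	0.529
GCA	A	16	0.941
GCG	A	9	0.529
UAU	Y	224	1.697
UAC	Y	40	0.303
UGA	*	72	1.049
UAG	*	40	0.583
UAA	*	94	1.369
CAU	H	29	1.055
CAC	H	26	0.945
CAA	Q	29	1.706
CAG	Q	5	0.294
AAU	N	216	1.459
AAC	N	80	0.541
AAA	K	134	1.403
AAG	K	57	0.597
GAU	D	53	1.797
GAC	D	6	0.203
GAG	E	14	0.667
GAA	E	28	1.333
UGU	C	73	1.315
UGC	C	38	0.685
UGG	W	63	1
CGU	R	10	1.053
CGC	R	7	0.737
CGA	R	17	1.789
CGG	R	4	0.421
AGA	R	58	0.967
AGG	R	62	1.033
AGU	S	84	1.084
AGC	S	71	0.916
GGU	G	29	1.036
GGC	G	18	0.643
GGA	G	36	1.286
GGG	G	29	1.036
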