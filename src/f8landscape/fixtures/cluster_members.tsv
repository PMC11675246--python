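cluster	residue
1	I2100
1	Y2124
1	S2125
2	Y2116
2	S2082
2	A2108
3	Y1717
3	E1756
3	I1756
4	W1854
4	D1859
4	D1861
5	R22
5	T154
5	V159
6	D169
6	T174
6	F214
6	P309
6	T314
6	A315
7	L480
7	V534
7	L571
7	K575
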