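cluster	vus_residue	partner_chain	partner_aa	partner_resnum	correlation
1	I2100	F8	ILE	2099	0.984
1	I2100	F8	HIS	2101	0.984
1	I2100	F8	GLY	2102	0.972
1	I2100	F8	PRO	2162	0.969
1	I2100	F8	LEU	2185	0.969
1	I2100	F8	GLU	2184	0.958
1	I2100	F8	PHE	2145	0.947
1	I2100	F8	MET	2183	0.944
1	I2100	F8	PHE	2120	0.937
1	I2100	F8	TYR	2124	0.931
1	I2100	F8	PHE	2146	0.926
1	I2100	F8	ARG	2182	0.92
1	I2100	F8	ASP	2093	0.916
1	I2100	F8	SER	2125	0.914
1	I2100	F8	ARG	2169	0.913
1	I2100	F8	PRO	2172	0.913
1	I2100	F8	ASN	2148	0.909
1	I2100	F8	THR	2173	0.909
1	I2100	F8	LYS	2091	0.908
1	I2100	F8	ARG	2135	0.905
1	I2100	F8	SER	2192	0.9
2	Y2116	VWF	LEU	797	0.945
2	Y2116	VWF	ASN	794	0.941
2	Y2116	VWF	GLU	798	0.93
2	Y2116	VWF	GLN	793	0.924
2	Y2116	VWF	CYS	799	0.923
2	Y2116	VWF	THR	791	0.922
2	Y2116	VWF	LYS	790	0.917
2	Y2116	VWF	TYR	795	0.917
2	Y2116	VWF	ASP	796	0.916
2	Y2116	VWF	CYS	792	0.911
2	Y2116	VWF	CYS	788	0.902
3	E1756	F8	PHE	1794	0.963
3	E1756	F8	GLY	1779	0.952
3	E1756	F8	ARG	1768	0.952
3	E1756	F8	LEU	1775	0.95
3	E1756	F8	GLN	1764	0.945
3	E1756	F8	PRO	1873	0.932
3	E1756	F8	GLY	1769	0.923
3	E1756	F8	LEU	1951	0.914
3	E1756	F8	GLU	1770	0.902
3	Y1717	VWF	LEU	765	0.925
3	Y1717	VWF	SER	764	0.913
3	Y1717	VWF	SER	766	0.902
4	W1854	F8	ALA	1853	0.956
4	W1854	F8	PRO	1873	0.934
4	W1854	F8	SER	1806	0.927
4	W1854	F8	MET	1791	0.916
7	K575	F8	SER	577	0.953
7	K575	F8	CYS	547	0.953
7	K575	F8	ARG	546	0.941
7	K575	F8	THR	541	0.913
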