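variant	group	conservation	total_score	gnomad_allele_count	geno2mp_homozygous	gnomad_homozygote	CADD_PHRED	SIFT	PolyPhen
P309L	ClinVar_VUS	0.95	15.31	0	0	0	26.2	deleterious	probably_damaging
W1854C	ClinVar_VUS	1.00	15.23	0	0	0	26.4	deleterious	probably_damaging
Y2134H	ClinVar_VUS	1.00	15.00	0	0	0	26.1	deleterious	probably_damaging
Y2116H	ClinVar_VUS	0.99	14.99	0	0	0	26.8	deleterious	probably_damaging
D2150V	ClinVar_VUS	0.99	14.92	0	0	0	28.6	deleterious	probably_damaging
D169N	ClinVar_VUS	1.00	14.85	0	0	0	25.6	deleterious	probably_damaging
T174I	ClinVar_VUS	1.00	14.77	0	0	0	24.7	deleterious	probably_damaging
G92S	ClinVar_VUS	1.00	14.76	0	0	0	24.8	deleterious	probably_damaging
A2237S	ClinVar_VUS	0.99	14.55	0	0	0	24.9	deleterious	probably_damaging
L571R	ClinVar_VUS	1.00	14.50	0	0	0	26.4	deleterious	probably_damaging
T2004A	ClinVar_VUS	1.00	14.45	0	0	0	25.7	deleterious	probably_damaging
D1861G	ClinVar_VUS	0.87	14.43	0	0	0	26.1	deleterious	probably_damaging
N486I	ClinVar_VUS	0.99	14.24	0	0	0	26.1	deleterious	probably_damaging
V2251M	ClinVar_VUS	0.98	14.18	0	0	0	24.6	deleterious	probably_damaging
T314P	ClinVar_VUS	0.99	14.17	0	0	0	25.2	deleterious	probably_damaging
I2100T	ClinVar_VUS	0.89	14.13	0	0	0	24.4	deleterious	probably_damaging
G525R	ClinVar_VUS	0.92	14.12	4	0	0	25.1	deleterious	probably_damaging
G2063E	Geno2MP	0.98	14.07	0	0	0	28.8	deleterious	probably_damaging
L480P	ClinVar_VUS	0.61	14.06	0	0	0	25.7	deleterious	probably_damaging
E1756V	ClinVar_VUS	0.95	13.97	0	0	0	27.4	deleterious	probably_damaging
S2125T	ClinVar_VUS	0.96	13.94	45	0	0	24.7	deleterious	probably_damaging
A2108P	ClinVar_VUS	0.99	13.85	0	0	0	24.2	deleterious	probably_damaging
R1768S	Geno2MP	0.98	13.71	0	0	0	25.6	deleterious	probably_damaging
Y1717H	ClinVar_VUS,Geno2MP	1.00	13.65	3	0	0	25.8	deleterious	probably_damaging
R22K	ClinVar_VUS	0.98	13.43	0	0	0	25.9	deleterious	probably_damaging
F1849I	ClinVar_VUS	0.98	13.43	0	0	0	26	deleterious	probably_damaging
E30G	ClinVar_VUS	0.96	13.35	0	0	0	23.7	deleterious	probably_damaging
K82E	ClinVar_VUS	0.98	13.28	0	0	0	24.8	deleterious	probably_damaging
A394D	ClinVar_VUS	0.97	13.27	0	0	0	25.2	deleterious	probably_damaging
D1859V	ClinVar_VUS	0.58	13.24	0	0	0	26	deleterious	probably_damaging
K575T	ClinVar_VUS	0.98	13.13	1	0	0	24.6	deleterious	probably_damaging
T154I	ClinVar_VUS	0.96	13.05	1	0	0	24.3	deleterious	probably_damaging
S2082N	ClinVar_VUS,UniProt	0.97	13.03	0	0	0	24.6	deleterious	probably_damaging
A315G	ClinVar_VUS	0.98	13.01	0	0	0	24.6	deleterious	probably_damaging
Y2214C	Geno2MP	0.70	12.98	7	0	0	25.6	deleterious	probably_damaging
D1685G	Geno2MP	0.70	12.86	0	2	0	25.2	deleterious	probably_damaging
V534A	ClinVar_VUS,Geno2MP	0.74	12.80	2	1	0	25.6	deleterious	probably_damaging
A2108V	ClinVar_VUS,Geno2MP	0.99	12.56	1	1	0	25.4	deleterious	possibly_damaging
D2317A	Geno2MP	0.62	12.50	3	1	0	25.2	deleterious	probably_damaging
F214Y	ClinVar_VUS	0.92	12.49	1	0	0	24.9	deleterious	probably_damaging
V159A	ClinVar_VUS,UniProt	0.52	12.33	0	0	0	24.9	deleterious	possibly_damaging
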