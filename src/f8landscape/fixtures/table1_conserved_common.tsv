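variant	conservation	group	gnomad_homozygote	gnomad_hemizygote	gnomad_overall_af	gnomad_max_af	max_af_population	geno2mp_homozygous	phenotypes
E340K	0.96	UniProt,Geno2MP	0	45	7.61E-05	1.39E-03	South Asian	2	Nephrotic syndrome, Abnormal muscle physiology
E1690G	0.87	Geno2MP	0	2	2.37E-05	8.28E-04	East Asian	0	Bladder exstrophy
S2125T	0.96	ClinVar_VUS	0	14	3.73E-05	4.58E-04	Middle Eastern	0	Hereditary factor VIII deficiency disease
N583S	0.99	UniProt	1	17	1.82E-05	3.52E-04	South Asian	0	-
T2256S	0.86	Geno2MP	0	3	1.16E-05	3.06E-04	Admixed American	1	Fatigable weakness
Y657H	0.94	ClinVar_VUS	0	3	6.38E-06	2.42E-04	Middle Eastern	0	Hereditary factor VIII deficiency disease
Q1764R	0.89	ClinVar_Path,Geno2MP	0	56	1.32E-04	2.31E-04	Remaining	1	Thrombophilia, Heterotaxy
R458H	0.93	ClinVar_Path,Geno2MP	0	20	4.96E-05	2.29E-04	Middle Eastern	0	Abnormality of hindbrain morphology
R612H	0.91	ClinVar_VUS,Geno2MP	0	7	2.48E-05	2.29E-04	Middle Eastern	1	Aplasia cutis congenita, Hereditary factor VIII deficiency disease
K344Q	0.77	Geno2MP	0	4	9.92E-06	2.28E-04	Middle Eastern	0	Ebstein's anomaly of the tricuspid valve
P1707L	0.82	Geno2MP	0	19	4.88E-05	1.98E-04	Admixed American	3	Retinal degeneration
P1265Q	0.75	Geno2MP	0	6	1.24E-05	1.94E-04	South Asian	0	Nephrotic syndrome
D364N	0.74	Geno2MP	0	7	1.16E-05	1.75E-04	Admixed American	0	Progressive muscle weakness
R2166Q	0.92	Geno2MP	0	15	4.64E-05	1.23E-04	South Asian	2	Abnormality of limbs
P83R	0.83	UniProt,ClinVar_Path	0	3	8.22E-06	1.14E-04	Admixed American	0	Hereditary factor VIII deficiency disease
R2016Q	0.95	ClinVar_Path	0	3	8.20E-06	1.14E-04	African/African American	0	Hereditary factor VIII deficiency disease
Q1955E	0.92	ClinVar_VUS	0	0	2.73E-06	1.14E-04	African/African American	0	Hereditary factor VIII deficiency disease
E2023K	0.95	ClinVar_Path	0	4	1.16E-05	1.09E-04	Admixed American	0	Thrombophilia
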