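accession	log2fc	q_mod	description	n_peptides	id_fdr_max
P01011	1.316	0.030	Alpha-1-antichymotrypsin	31	0.01
A0A1B0GWE8	1.439	0.046	Cathepsin D	29	0.01
P10523	4.277	0.000	S-arrestin	27	0.01
P36222	2.538	0.008	Chitinase-3-like protein1	26	0.01
B4DPQ0	1.341	0.033	Complement subcomponent C1r	25	0.01
P02788	2.487	0.029	Lactotransferrin	22	0.01
Q17R60	3.535	0.000	Interphotoreceptor matrix proteoglycan1	22	0.01
A0A7I2V2D2	1.431	0.032	Plasma protease C1 inhibitor	20	0.01
P62873	3.122	0.016	Guanine nucleotide-binding protein G(I)/G(S)/G(T) subunit beta-1	19	0.01
P02042	3.110	0.019	Hemoglobin subunit delta	15	0.01
P08571	1.418	0.012	Monocyte differentiation antigen CD14	15	0.01
P07858	1.488	0.025	Cathepsin B	12	0.01
P69905	3.407	0.048	Hemoglobin subunit alpha	12	0.01
Q9BZV3	3.479	0.004	Interphotoreceptor matrix proteoglycan2	12	0.01
P01033	1.686	0.020	Metalloproteinase inhibitor1	11	0.01
Q6EMK4	2.422	0.005	Vasorin	11	0.01
P07602	1.946	0.016	Prosaposin	10	0.01
Q92743	1.469	0.044	Serine protease HTRA1	10	0.01
P08779	1.364	0.048	Keratin, type I cytoskeletal16	9	0.01
P61769	1.301	0.046	Beta-2-microglobulin	9	0.01
P63211	5.403	0.000	Guanine nucleotide-binding protein G(T) subunit gamma-T1	7	0.01
Q96JP9	2.445	0.005	Cadherin-related family member1	6	0.01
D6RHI9	1.484	0.038	Ribonuclease T2 (Fragment)	5	0.01
P07205	2.584	0.032	Phosphoglycerate kinase2	5	0.01
P55058	2.086	0.002	Phospholipid transfer protein	5	0.01
Q8N114	3.579	0.001	Protein shisa-5	4	0.01
Q9HCQ7	2.668	0.008	Pro-FMRFamide-related neuropeptide VF	4	0.01
B3KRD8	3.275	0.046	Section 14-like 2 (S. cerevisiae), isoform CRA_c	3	0.01
E9PEK4	2.488	0.004	Receptor protein-tyrosine kinase	3	0.01
O95897	2.549	0.008	Noelin-2	3	0.01
P29279	1.957	0.002	CCN family member2	3	0.01
Q14974	3.193	0.016	Importin subunit beta-1	3	0.01
Q8NBJ4	1.542	0.004	Golgi membrane protein1	3	0.01
A0A7P0T9A7	3.187	0.032	Adenylosuccinate lyase	2	0.01
B0QYH5	3.626	0.001	Seizure 6-like protein	2	0.01
H0YBL1	3.495	0.009	Inositol-1-monophosphatase (Fragment)	2	0.01
P17936	1.198	0.032	Insulin-like growth factor-binding protein3	2	0.01
P30740	4.397	0.009	Leukocyte elastase inhibitor	2	0.01
Q9NP84	2.029	0.012	Tumor necrosis factor receptor superfamily member 12 A	2	0.01
Q9UHI8	1.696	0.029	A disintegrin and metalloproteinase with thrombospondin motifs1	2	0.01
A0A2R8YFQ7	1.507	0.021	Lambda-crystallin homolog	1	0.05
A0A8Q3WKS4	1.206	0.040	Lactadherin	1	0.01
E9PK73	5.529	0.001	Succinate dehydrogenase [ubiquinone] cytochrome b small subunit	1	0.05
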