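accession	log2fc	q_mod	description	n_peptides	id_fdr_max
P00352	-3.349	0.033	Aldehyde dehydrogenase 1A1	42	0.01
P53674	-3.459	0.045	Beta-crystallin B1	42	0.01
P48637	-3.230	0.026	Glutathione synthetase	31	0.01
P05813	-3.819	0.048	Beta-crystallin A3	27	0.01
P29401	-3.434	0.035	Transketolase	25	0.01
Q00796	-3.047	0.032	Sorbitol dehydrogenase	18	0.01
P53672	-4.549	0.001	Beta-crystallin A2	17	0.01
P04792	-3.898	0.010	Heat shock protein beta-1	11	0.01
Q5TDP6	-3.195	0.048	Lengsin	10	0.01
Q93088	-3.076	0.029	Betaine–homocysteine S-methyltransferase1	8	0.01
Q96GW7	-2.168	0.013	Brevican core protein	8	0.01
P15121	-3.143	0.013	Aldo-keto reductase family 1 member B1	7	0.01
P30041	-3.447	0.000	Peroxiredoxin-6	7	0.01
P00390	-2.319	0.029	Glutathione reductase, mitochondrial	6	0.01
P07900	-2.578	0.028	Heat shock protein HSP 90-alpha	6	0.01
P0DOX3	-3.374	0.001	Immunoglobulin delta heavy chain	5	0.01
P22061	-2.093	0.046	Protein-L-isoaspartate(D-aspartate) O-methyltransferase	5	0.01
P38606	-2.371	0.020	V-type proton ATPase catalytic subunit A	4	0.01
P13798	-2.618	0.006	Acylamino-acid-releasing enzyme	3	0.01
P40227	-3.349	0.001	T-complex protein 1 subunit zeta	3	0.01
E9PQW4	-1.622	0.025	Mitogen-activated protein kinase	2	0.01
O75347	-1.741	0.005	Tubulin-specific chaperone A	2	0.01
P07737	-2.689	0.004	Profilin-1	2	0.01
P13489	-2.265	0.001	Ribonuclease inhibitor	2	0.01
Q14764	-3.119	0.001	Major vault protein	2	0.01
Q96C23	-1.999	0.012	Galactose mutarotase	2	0.01
A0A0A0MS98	-3.022	0.001	Band 3 anion transport protein	1	0.05
B1AK87	-1.412	0.048	F-actin-capping protein subunit beta	1	0.05
D6RA82	-5.612	0.000	Annexin	1	0.05
D6RAY0	-2.175	0.002	Alcohol dehydrogenase class-3	1	0.01
E9PLN1	-2.688	0.033	UPF0686 protein C11orf1	1	0.05
H0Y8C6	-2.046	0.048	Importin-5 (Fragment)	1	0.01
O00515	-3.770	0.001	Ladinin-1	1	0.05
P01601	-1.796	0.015	Immunoglobulin kappa variable 1D-16	1	0.05
P26447	-2.418	0.001	Protein S100-A4	1	0.05
P49773	-2.017	0.034	Adenosine 5’-monophosphoramidase HINT1	1	0.05
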