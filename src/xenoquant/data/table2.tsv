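accession	protein_name	gene	peptides	p_value	fold_change
O60437	Periplakin	PPL	2	3.34e-8	7.85
P36952	Serpin B5	SERPINB5	7	2.37e-3	4.86
P54868	Hydroxymethylglutaryl-CoA synthase, mitochondrial	HMGCS2	3	4.29e-3	4.79
O95833	Chloride intracellular channel protein 3	CLIC3	2	6.99e-3	3.62
P16144	Integrin beta-4	ITGB4	2	6.03e-4	3.35
Q96FQ6	Protein S100-A16	S100A16	3	9.17e-4	3.28
P27216	Annexin A13	ANXA13	6	2.72e-3	3.27
Q9HCY8	Protein S100-A14	S100A14	4	5.20e-3	3.09
O60218	Aldo-keto reductase family 1-member B10	AKR1B10	3	2.04e-2	3.03
P11047	Laminin subunit gamma-1	LAMC1	2	9.87e-3	2.97
Q12864	Cadherin-17	CDH17	4	2.27e-2	2.81
P09327	Villin-1	VIL1	3	5.26e-4	2.68
Q9H190	Syntenin-2	SDCBP2	2	1.15e-3	2.67
P05787	Keratin, type II cytoskeletal 8	KRT8	5	1.51e-2	2.63
P15311	Ezrin	EZR	2	2.79e-3	2.60
P56470	Galectin-4	LGALS4	7	1.09e-2	2.58
Q14764	Major vault protein	MVP	5	2.31e-3	2.42
Q8NFV4	Alpha/beta hydrolase domain-containing protein 11	ABHD11	4	6.45e-3	2.40
P42765	3-ketoacyl-CoA thiolase, mitochondrial	ACAA2	2	7.25e-4	2.14
P99999	Cytochrome c	CYCS	2	6.30e-3	2.14
P08727	Keratin, type I cytoskeletal 19	KRT19	9	2.03e-2	2.11
P17931	Galectin-3	LGALS3	2	1.92e-2	2.10
P55011	Solute carrier family 12 member 2	SLC12A2	2	2.33e-2	2.04
P22307	Non-specific lipid-transfer protein	SCP2	2	2.01e-2	1.99
P09972	Fructose-bisphosphate aldolase C	ALDOC	2	1.83e-3	1.94
P12830	Cadherin-1	CDH1	3	1.57e-3	1.88
Q14126	Desmoglein-2	DSG2	4	7.28e-5	1.84
Q96I24	Far upstream element-binding protein 3	FUBP3	2	1.23e-2	1.83
Q02218	2-oxoglutarate dehydrogenase, mitochondrial	OGDH	2	1.60e-3	1.82
Q9NR45	Sialic acid synthase	NANS	3	1.48e-2	1.61
P14618	Pyruvate kinase PKM	PKM	3	3.90e-2	1.56
P55072	Transitional endoplasmic reticulum ATPase	VCP	2	1.50e-2	1.51
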