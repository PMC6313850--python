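accession	protein_name	gene	peptides	p_value	fold_change
P18564	Integrin beta-6	ITGB6	2	8.80e-3	8.69
P02751	Fibronectin	FN1	3	4.67e-2	7.95
P07996	Thrombospondin-1	THBS1	5	2.56e-2	7.65
Q15063	Periostin	POSTN	8	2.06e-2	7.34
O14498	Immunoglobulin superfamily containing leucine-rich repeat protein	ISLR	2	4.27e-2	7.10
P31947	14-3-3 protein sigma	SFN	3	1.19e-3	6.06
P35442	Thrombospondin-2	THBS2	5	1.33e-2	6.02
O43294	Transforming growth factor beta-1-induced transcript 1 protein	TGFB1I1	2	5.98e-3	5.75
Q8IUX7	Adipocyte enhancer-binding protein 1	AEBP1	3	1.72e-2	5.59
P08174	Complement decay-accelerating factor	CD55	2	8.43e-4	5.58
Q03518	Antigen peptide transporter 1	TAP1	2	4.62e-3	5.00
Q03519	Antigen peptide transporter 2	TAP2	2	2.42e-2	4.24
O15533	Tapasin	TAPBP	2	1.14e-2	4.07
P23142	Fibulin-1	FBLN1	6	1.44e-2	3.81
Q08380	Galectin-3-binding protein	LGALS3BP	3	7.24e-3	3.80
P50454	Serpin H1	SERPINH1	2	5.73e-4	3.64
P02792	Ferritin light chain	FTL	3	3.77e-2	3.56
P98095	Fibulin-2	FBLN2	2	1.10e-2	3.41
P20592	Interferon-induced GTP-binding protein Mx2	MX2	2	2.43e-4	3.38
Q6UX06	Olfactomedin-4	OLFM4	3	4.26e-2	3.27
Q01518	Adenylyl cyclase-associated protein 1	CAP1	2	3.22e-2	3.22
Q01995	Transgelin	TAGLN	6	2.51e-2	3.20
Q96HE7	ERO1-like protein alpha	ERO1A	11	2.39e-3	3.16
Q92597	Protein NDRG1	NDRG1	2	3.28e-2	3.15
Q6PIU2	Neutral cholesterol ester hydrolase 1	NCEH1	4	1.51e-5	3.13
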