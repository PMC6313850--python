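accession	protein_name	highest_in	gene	peptides	p_value	fold_change
O75874	Isocitrate dehydrogenase [NADP] cytoplasmic	pdx_f2	IDH1	2	1.22e-2	1.60
P07339	Cathepsin D	pdx_f2	CTSD	2	2.06e-2	1.62
P30041	Peroxiredoxin-6	pdx_f2	PRDX6	2	2.18e-2	1.81
P00352	Retinal dehydrogenase 1	pdx_f2	ALDH1A1	4	2.36e-2	1.76
P35237	Serpin B6	pdx_f2	SERPINB6	2	2.85e-2	1.87
P02768	Serum albumin	pdx_f1	ALB	3	3.26e-2	5.15
P04083	Annexin A1	pdx_f1	ANXA1	3	3.92e-2	2.41
P08133	Annexin A6	pdx_f1	ANXA6	2	4.19e-2	2.58
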