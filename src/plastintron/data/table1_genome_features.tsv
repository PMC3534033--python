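tag	species	at_percent	total_bp	genes_bp	intergenic_bp	introns_bp	coding_pct	intergenic_pct	intronic_pct	genes_total	protein_coding	trnas	rrnas	insertion_sites	intron_orfs	rrna_operons
Egra	Euglena gracilis	73.9	143171	62776	24712	55683	43.8	17.3	38.9	88	58	27	3	139	4	3
Elon	Euglena longa	77.6	73345	49860	11357	12128	68.0	15.5	16.5	57	27	27	3	60	0	3
Maen	Monomorphina aenigmatica	70.6	74746	45568	13048	16130	61.0	17.5	21.6	87	58	27	2	53	3	1
Evir	Eutreptia viridis	71.4	65513	44061	9288	12164	67.3	14.2	18.6	84	56	25	3	23	3	2
Egym	Eutreptiella gymnastica	65.7	67622	50573	10176	6873	74.8	15.0	10.2	86	58	26	2	7	4	2
Ppar	Pyramimonas parkeae	65.3	101605	80191	18657	2757	78.9	18.4	2.7	110	81	27	2	1	1	2
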