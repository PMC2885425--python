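# field_frequency_MHz = 600.13
# 1H chemical shift assignment of the amyloid-beta 12-28 fragment in the
# presence of the naphthoquinone-tryptophan ligand (row NQT, index 0).
residue_index	residue_name	nucleus	shift_ppm
12	VAL	HA	3.72
13	HIS	HN	8.89
13	HIS	HA	4.66
14	HIS	HN	8.73
14	HIS	HA	4.66
15	GLN	HN	8.59
15	GLN	HA	4.28
16	LYS	HN	8.48
16	LYS	HA	4.24
17	LEU	HN	8.32
17	LEU	HA	4.31
18	VAL	HN	7.96
18	VAL	HA	4.01
19	PHE	HN	8.21
19	PHE	HA	4.54
20	PHE	HN	8.14
20	PHE	HA	4.54
21	ALA	HN	8.26
21	ALA	HA	4.19
22	GLU	HN	8.28
22	GLU	HA	4.24
23	ASP	HN	8.39
23	ASP	HA	4.65
24	VAL	HN	8.07
24	VAL	HA	4.11
25	GLY	HN	8.50
25	GLY	HA	3.94
26	SER	HN	8.13
26	SER	HA	4.42
27	ASN	HN	8.45
27	ASN	HA	4.70
28	LYS	HN	7.87
28	LYS	HA	4.13
0	NQT	HN	7.04
0	NQT	HA	4.23
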