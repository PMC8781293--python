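protein	pdb_id	resolution	n_protein_atoms	n_ligand_atoms	n_torsions
GNB/LNB-binding protein	2Z8D	1.9	5897	51	6
GNB/LNB-binding protein	2Z8E	2.0	5897	51	6
alpha-fucosidase	2XII	1.8	7042	51	4
KIV-10 module of Apo(a)	3KIV	1.8	1206	20	5
BET protein	4MR5	1.6	1860	42	3
BET protein	4MR6	1.7	1860	49	6
CRP	1HW5	1.8	3284	33	1
Trypsin	1C5P	1.4	3220	18	1
Trypsin	1K1J	2.2	3220	68	10
Trypsin	2ZDM	1.9	3220	59	9
Trypsin	2ZDN	2.0	3220	58	9
Trypsin	2ZFS	1.5	3220	64	9
YKL-39	4P8V	1.6	5741	57	8
Factor XIa	4CRC	1.6	3711	60	11
Factor XIa	4CRD	2.1	3692	57	11
EngF	1J84	2.0	2642	87	10
Mp1p-LBD2	5CSD	1.5	2407	53	14
HIV-1 protease	1MRX	2.0	3140	74	11
HIV-1 protease	1MSM	2.0	3138	78	12
HIV-1 protease	2PYM	1.9	3100	86	12
HIV-1 protease	2PYN	1.9	3116	86	12
HIV-1 protease	3KDB	1.7	3138	86	13
HIV-1 protease	3NU3	1.0	3134	70	13
HIV-1 protease	4LL3	2.0	3134	75	13
Renin	2IKO	1.9	5144	46	5
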