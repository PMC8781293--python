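pdb_id	n_min	inn_pm6d3h4x_cosmo	rmsd_pm6d3h4x_cosmo	inn_pm7_cosmo	rmsd_pm7_cosmo
1C5P	5349	1	0.44	1	0.43
1HW5	6848	1	0.48	1	0.48
1J84	8192	11	5.64	1	1.97
1K1J	8101	1	0.33	1	0.33
1MRX	2627	1	1.35	1	0.47
1MSM	6030	1	1.87	1	1.87
2IKO	2622	1	0.49	1	0.49
2PYM	4340	1	1.66	1	1.66
2PYN	4953	1	1.22	1	1.22
2XII	8192	1	0.58	1	0.58
2Z8D	8192	5	3.67	2	3.67
2Z8E	8192	1	1.11	1	1.11
2ZDM	5971	1	0.91	1	0.91
2ZDN	5645	8	2.12	1	0.68
2ZFS	5986	9	2.67	2	2.67
3KDB	4504	2	2.61	1	0.96
3KIV	5363	1	0.84	1	0.75
3NU3	4935	1	0.44	1	0.44
4CRC	11809	2	2.67	2	2.67
4CRD	20222	233	10.81	1	1.00
4LL3	5888	3	11.67	4	8.38
4MR5	5002	2	8.05	5	8.05
4MR6	4313	1	1.16	1	1.16
4P8V	8193	37	10.11	1	0.58
5CSD	29528	2576	10.33	993	10.33
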