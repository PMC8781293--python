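pdb_id	dh_exp	dh_pm6d3h4x_cosmo	dh_pm7_cosmo
1C5P	-4.52	-27.70	-54.75
1HW5	-0.97	-37.04	-54.74
1K1J	-9.46	-29.62	-82.71
1MRX	-2.10	-9.36	-54.89
1MSM	-7.60	-20.13	-67.86
2IKO	-9.50	-33.81	-81.19
2XII	-9.80	-72.28	-92.09
2ZDM	-7.24	-30.73	-82.20
2ZDN	-5.09		-85.08
3KDB	-1.55		-54.68
3NU3	-7.30	-6.78	-54.46
4MR6	-4.04	-15.27	-47.42
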