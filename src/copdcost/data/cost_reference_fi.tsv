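year	component	eur	eur_per_100k
1996	outpatient_shc	3890214	75798
1996	hospital_shc	35321979	688226
1996	hospital_phc	7371664	143632
1996	medication	17046441	332139
1996	total_direct	63630298	1239796
1996	sickness_allowance	4897021	95415
1996	disability_pension	41592319	810400
1996	total_indirect	46489340	905815
1996	total	110119638	2145611
2006	outpatient_shc	4023000	76237
2006	hospital_shc	19154939	362992
2006	hospital_phc	9835330	186383
2006	medication	23268935	440954
2006	total_direct	56282204	1066566
2006	sickness_allowance	6074400	115112
2006	disability_pension	45348966	859378
2006	total_indirect	51423366	974489
2006	total	107705570	2041055
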