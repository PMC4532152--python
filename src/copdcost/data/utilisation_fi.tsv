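year	population	phc_hospital_days	shc_hospital_days	shc_outpatient_visits	sickness_allowance_days	disability_pension_subjects	medication_cost
1996	5132320	58986	68231	22179	59104	1928	17046441
2006	5276955	69021	32446	20115	64354	1844	23268935
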