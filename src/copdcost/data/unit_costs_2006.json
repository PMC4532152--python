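{
  "phc_hospital_day": 142,
  "shc_hospital_day": 590,
  "shc_outpatient_visit": 200,
  "lost_man_year": 24600,
  "reference_year": 2006
}
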