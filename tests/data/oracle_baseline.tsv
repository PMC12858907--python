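case	oracle_value
t1_glc10_fba	10.000000000
t1_cit100_fba	0.000000000
pair_no_limitation_total	15.000000000
pair_equal_abundance_mu	5.000000000
pair_target_B	5.000000000
dhp_DH_C2_total	62.500000000
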