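# Observed structural-damage counts among unique NC1 missense variants in
# the LOVD disease-variant database, with the expected percentage of each
# feature under the neighbour-dependent substitution-rate null model.
# cohort "all": n = 86 unique substitutions; cohort "noncys": Cys
# substitutions excluded, n = 57.  p_printed is the published p-value
# ("<0.001" where below reporting precision); disulphide breakage is not
# applicable once Cys substitutions are removed.
cohort	n	feature	observed_k	expected_pct	p_printed
all	86	any_structural_damage	46	19.2	<0.001
all	86	buried_charge_introduced	8	3.4	0.01
all	86	buried_charge_replaced	0	1.2	0.63
all	86	buried_charge_switch	0	0.5	1
all	86	buried_gly_replaced	7	1.2	<0.001
all	86	buried_hbond_breakage	4	4.5	0.80
all	86	buried_hydrophilic_introduced	5	1.6	0.01
all	86	buried_pro_introduced	0	1.3	0.63
all	86	buried_salt_bridge_breakage	0	1.0	1
all	86	buried_exposed_switch	2	1.7	0.66
all	86	cavity_altered	1	0.6	0.39
all	86	clash	14	2.7	<0.001
all	86	disallowed_phi_psi	3	3.0	0.75
all	86	disulphide_breakage	29	5.5	<0.001
all	86	gly_in_bend	0	0.4	1
all	86	secondary_structure_altered	1	1.0	0.60
noncys	57	any_structural_damage	17	14.5	0.004
noncys	57	buried_charge_introduced	4	2.9	0.08
noncys	57	buried_charge_replaced	0	1.3	1
noncys	57	buried_charge_switch	0	0.5	1
noncys	57	buried_gly_replaced	7	1.3	<0.001
noncys	57	buried_hbond_breakage	4	4.8	0.35
noncys	57	buried_hydrophilic_introduced	1	0.9	0.40
noncys	57	buried_pro_introduced	0	1.4	1
noncys	57	buried_salt_bridge_breakage	0	1.1	1
noncys	57	buried_exposed_switch	2	1.6	0.23
noncys	57	cavity_altered	1	0.6	0.29
noncys	57	clash	3	1.0	0.02
noncys	57	disallowed_phi_psi	3	3.2	0.43
noncys	57	gly_in_bend	0	0.4	1
noncys	57	secondary_structure_altered	1	1.1	0.47
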