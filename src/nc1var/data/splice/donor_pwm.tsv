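# Donor (5') splice-site base frequencies over the 9-mer window
# (3 exonic positions, then 6 intronic beginning GT).  Packaged default
# for the log-odds PWM scorer; reflects the canonical MAG|GTRAGT
# consensus of human donor sites.
position	A	C	G	T
-3	0.33	0.36	0.18	0.13
-2	0.60	0.13	0.14	0.13
-1	0.08	0.04	0.81	0.07
1	0.003	0.003	0.990	0.004
2	0.003	0.003	0.004	0.990
3	0.595	0.030	0.350	0.025
4	0.71	0.08	0.12	0.09
5	0.06	0.05	0.82	0.07
6	0.15	0.17	0.22	0.46
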