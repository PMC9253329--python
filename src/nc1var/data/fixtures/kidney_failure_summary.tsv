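# Family-level kidney-failure summaries for males with collagen IV alpha-5
# missense variants in LOVD.  Median/IQR in years; p_printed compares each
# group with the Cys NC1 group by the log-rank test.
group	n_families	n_kidney_failure	median	q1	q3	p_printed
cys_nc1	13	9	31	16	33
noncys_nc1	22	13	34.5	22	39	0.23
gly_collagenous	157	129	26	21	35	0.77
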