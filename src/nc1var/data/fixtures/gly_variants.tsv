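# Curated Gly-substitution tallies for the collagen IV alpha-5 NC1 domain.
# The domain carries 4 buried Gly residues (all conserved across the six
# human alpha-chains) and 13 non-buried Gly residues.  splice_note marks
# variants whose DNA change affects splicing rather than producing the
# nominal missense product; these are excluded from missense analyses.
residue	buried	conserved	db	alt_aa	n_families	label	splice_note
1492	yes	yes	LOVD	R	3	P/LP
1492	yes	yes	LOVD	A	5	P/LP
1492	yes	yes	LOVD	D	3	P
1492	yes	yes	LOVD	V	2	LP
1492	yes	yes	ClinVar	A	2	VUS
1492	yes	yes	ClinVar	D	1	P
1510	yes	yes	ClinVar	R	1	P	c.4528G>C predicted to affect splicing
1602	yes	yes	LOVD	C	2	P/LP
1602	yes	yes	LOVD	S	2	P/LP
1602	yes	yes	LOVD	V	4	P/LP
1602	yes	yes	ClinVar	D	2	P
1602	yes	yes	ClinVar	S	1	LP
1602	yes	yes	ClinVar	V	1	P
1624	yes	yes	100kGP	C	1
1624	yes	yes	gnomAD	A	1
1467	no	yes	gnomAD	A	1
1506	no	no	LOVD	S	1	LB
1506	no	no	100kGP	C	1
1506	no	no	100kGP	S	1
1506	no	no	gnomAD	C	3
1506	no	no	gnomAD	S	2
1506	no	no	gnomAD	V	1
1560	no	no	LOVD	D	1	VUS
1595	no	no	LOVD	V	1	P	c.4784G>T activates a cryptic splice site
1595	no	no	ClinVar	V	1	P	c.4784G>T activates a cryptic splice site
1675	no	no	LOVD	R	1	VUS
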