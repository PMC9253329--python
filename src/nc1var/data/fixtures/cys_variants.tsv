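# Curated Cys-substitution tallies for the collagen IV alpha-5 NC1 domain,
# by source database (LOVD = disease-variant repository, ClinVar, gnomAD =
# population database).  n_families counts independent families/reports.
residue	conserved	db	alt_aa	n_families	label
1482	yes	LOVD	G	2	LP
1482	yes	LOVD	F	1	P
1482	yes	ClinVar	F	1	P
1482	yes	ClinVar	W	1	P
1515	yes	LOVD	F	1	P
1515	yes	ClinVar	Y	1	VUS
1527	yes	LOVD	S	2	LP
1527	yes	gnomAD	S	1	
1533	yes	LOVD	R	1	LP
1533	yes	LOVD	F	1	LP
1570	yes	LOVD	R	1	P
1570	yes	LOVD	S	1	P
1570	yes	LOVD	Y	3	LP
1570	yes	ClinVar	R	1	P
1570	yes	ClinVar	F	1	LP
1570	yes	ClinVar	S	4	P
1573	yes	LOVD	R	4	P
1573	yes	LOVD	S	1	P
1573	yes	LOVD	Y	1	LP
1573	yes	ClinVar	R	1	P
1573	yes	ClinVar	S	1	P
1592	yes	LOVD	R	2	P/LP
1592	yes	LOVD	F	2	VUS/P
1592	yes	LOVD	Y	2	LP
1592	yes	ClinVar	R	1	P
1592	yes	ClinVar	F	1	P
1626	yes	LOVD	S	2	LP/P
1626	yes	ClinVar	S	1	VUS
1638	yes	LOVD	R	1	P
1638	yes	LOVD	S	1	P
1638	yes	LOVD	W	1	LP
1638	yes	LOVD	Y	4	P/LP
1638	yes	ClinVar	G	1	P
1638	yes	ClinVar	W	1	LP
1638	yes	ClinVar	Y	1	P
1644	yes	LOVD	S	1	LP
1644	yes	LOVD	W	1	LP
1644	yes	LOVD	Y	3	LP
1644	yes	ClinVar	R	1	VUS
1644	yes	ClinVar	S	1	P
1644	yes	ClinVar	Y	3	P
1684	yes	LOVD	R	1	P
1684	yes	LOVD	W	1	P
1684	yes	LOVD	Y	4	P/LP
1684	yes	ClinVar	R	1	P
1684	yes	ClinVar	W	1	P
1687	yes	LOVD	G	1	LP
1687	yes	LOVD	F	1	P
1687	yes	LOVD	Y	2	P
1687	yes	ClinVar	G	1	P
1687	yes	ClinVar	F	1	P
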