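form	resname	resseq	protein_atom	water	ligand_atom	type	distance
soaking	TYR	334	CE2		CAZ	NP	3.19
soaking	TYR	334	CZ		CAY	NP	3.37
soaking	TYR	334	OH		CAY	NP	3.30
soaking	TYR	334	OH		CAI	NP	3.14
soaking	TYR	334	OH		CAD	NP	3.33
soaking	SER	363	OG		NAM	NP	3.39
soaking	SER	363	OG		OAB	NP	3.40
soaking	ARG	380	NH2		NAN	NP	3.07
soaking	ASN	382	CG		OAR	NP	3.02
soaking	ASN	382	OD1		OAR	NP	2.91
soaking	ASN	382	OD1		CAF	NP	3.03
soaking	ASN	414	OD1	W445		HB	2.67
soaking				W445	OAB	HB	2.58
soaking	ARG	415	NH1		OAA	ES	3.51
soaking	ARG	415	NH1		OAQ	NP	3.05
soaking	ARG	415	NH2		NAP	NP	3.08
soaking	ARG	415	NH2		CAX	NP	3.20
soaking	ARG	415	NH2		CAU	NP	3.26
soaking	ARG	483	NE		OAC	ES	3.47
soaking	ARG	483	NH2		OAC	ES	3.44
soaking	SER	508	CB		OAC	NP	3.14
soaking	SER	508	OG		OAC	HB	2.74
soaking	SER	508	OG		CAT	NP	3.12
soaking	ALA	556	CB		CAV	NP	3.39
soaking	GLY	603	CA		CAK	NP	3.11
cocrystallization	TYR	334	CG		CAL	NP	3.34
cocrystallization	TYR	334	OH		NAO	HB	3.07
cocrystallization	ARG	336	NE		CAD	NP	3.25
cocrystallization	ARG	336	NE		CAI	NP	3.34
cocrystallization	ARG	336	NE		CAF	NP	3.39
cocrystallization	ARG	336	O	W413		HB	2.66
cocrystallization				W413	NAP	HB	2.50
cocrystallization	SER	363	CB		OAA	NP	3.10
cocrystallization	SER	363	OG		OAA	HB	2.57
cocrystallization	SER	363	OG		CAT	NP	3.21
cocrystallization	SER	363	OG		OAC	NP	3.31
cocrystallization	ARG	380	NE		OAC	HB	2.88
cocrystallization	ARG	380	CZ		OAC	NP	3.30
cocrystallization	ARG	380	NH2		OAC	HB	2.88
cocrystallization	ARG	380	NH2		OAQ	NP	3.22
cocrystallization	ASN	382	CB		OAC	NP	3.21
cocrystallization	ASN	382	ND2		OAC	HB	3.05
cocrystallization	ASN	382	ND2		OAQ	NP	3.31
cocrystallization	ASN	414	OD1	W433		HB	2.81
cocrystallization				W433	OAA	HB	3.07
cocrystallization	SER	602	OG	W424		HB	2.79
cocrystallization				W424	OAA	HB	2.90
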