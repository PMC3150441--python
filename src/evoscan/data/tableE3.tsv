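Chr	Pos	Ref	Alt	Zygosity	Annotation	Syn?	Gene
IV	475252	T	G	hom (Ref)->het	CDS	Y 403 D	RAD61
IV	1178957	G	T	hom (Ref)->het	CDS	V 98 L	SBE2
VI	200817	C	A	hom (Ref)->het	CDS	T 315 K	PES4
VI	215628	C	G	hom (Ref)->het	CDS	P 773 A	MET10
VIII	114175	A	G	hom (Ref)->het	CDS	L 248 P	GPA1
VIII	405592	G	T	hom (Ref)->het	CDS	C 876 F	RTT107
IX	301064	C	T	hom (Ref)->het	CDS	C 65 Y	YIL029C
XIII	46350	C	A	hom (Ref)->het	intergenic		CTK3/BUL2
XIV	155354	G	T	hom (Ref)->het	CDS	L 85 F	ORC5
XV	76249	C	A	hom (Ref)->het	CDS	T 617 K	ALR1
XVI	549444	C	A	hom (Ref)->het	CDS	P 320 Q	AEP3
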