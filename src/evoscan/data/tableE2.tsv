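Chr	Pos	Ref	Alt	Zygosity	Annotation	Syn?	Gene
II	589713	T	G	hom (Ref)->het	intergenic		FZO1/DTR1
III	52717	G	T	hom (Ref)->het	CDS	G 25 C	GID7
III	303345	A	G	hom (Ref)->het	intergenic		YCR101/2
IV	573016	G	T	hom (Ref)->het	CDS	V 790 F	MAK21
IV	677840	G	T	het->hom (Ref)	intergenic		FOB1/ALT2
VII	120132	G	T	hom (Ref)->het	CDS	T 259 K	MCM6
VII	845690	G	C	hom (Ref)->het	tRNA		tG(GCC)G1
VIII	85164	G	T	hom (Ref)->het	intergenic		YAP3/tRNA-Val
VIII	335011	G	T	hom (Ref)->het	CDS	T 218 N	YHR112C
VIII	490972		-G	hom (Ref)->het	CDS	-202aa	NVJ1
X	427840	G	T	hom (Ref)->het	CDS	C 895 F	CYR1
XII	898188	G	C	hom (Ref)->het	5' UTR		RPS29A
XIII	687242	C	A	hom (Ref)->het	CDS	V 15 L	YMR209C
XV	183953	C	A	hom (Ref)->het	CDS	L 758 I	AVO1
XV	466475	G	T	hom (Ref)->het	CDS	V 569 L	SGO1
XVI	549443	C	A	hom (Ref)->het	CDS	P 320 T	AEP3
XVI	549453	A	T	hom (Ref)->het	CDS	E 323 V	AEP3
XVI	549454	A	G	hom (Ref)->het	CDS	syn	AEP3
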