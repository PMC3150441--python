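Chr	Pos	Ref	Alt	Zygosity	Annotation	Syn?	Gene
II	706287	C	G	hom (Ref)->het	CDS	M 169 I	ALG7
VII	147966	G	A	hom (Ref)->het	intergenic		CDC55/RPS26A
VII	187253	G	C	hom (Ref)->het	CDS	V 399 L	SUA5
VII	332623	T	C	hom (Ref)->het	CDS	K 615 E	PAN2
IX	69914	G	C	hom (Ref)->hom (Alt)	CDS	N 1180 K	SLN1
XIII	729971	C	A	hom (Ref)->het	CDS	G 385 C	RRP5
XV	379626	T	C	hom (Ref)->het	intergenic		HST3/BUB3
XV	821295	A	G	hom (Ref)->het	CDS	syn	PNT1
XV	878199	T	C	hom (Ref)->hom (Alt)	intergenic		MBF1/BUD7
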