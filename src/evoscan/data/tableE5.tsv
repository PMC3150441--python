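Chr	Pos	Ref	Alt	Zygosity	Annotation	Syn?	Gene
VII	34321	A	T	hom (Ref)->het	CDS	syn	ZIP2
VII	126868	T	C	hom (Ref)->het	CDS	F 724 S	MDS3
VII	155424	G	T	hom (Ref)->het	CDS	P 197 T	STR3
VIII	389336	A	G	hom (Ref)->het	LTR		YHRCdelta10
IX	166517	C	A	hom (Ref)->het	intron		MOB1
X	566107	C	A	hom (Ref)->het	CDS	T 2231 K	TOR1
XI	644490	C	G	hom (Ref)->het	intergenic		SIR1/FLO10
XII	933374	T	C	hom (Ref)->hom (Alt)	CDS	syn	YLR407W
XV	237964	C	A	hom (Ref)->het	CDS	P 1009 Q	GAL11
XV	452940	T	A	hom (Ref)->het	CDS	I 175 F	ALG8
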