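Chr	Pos	Ref	Alt	Zygosity	Annotation	Syn?	Gene
II	40357	A	T	hom (Ref)->het	CDS	I 405 L	BNA4
II	336311	C	G	hom (Ref)->het	CDS	A 170 P	REB1
II	649740	G	A	hom (Ref)->het	CDS	V 619 I	NGR1
IV	63483	C	A	hom (Ref)->het	CDS	Q 512 H	CDC13
IV	1154148	T	C	hom (Ref)->het	intergenic		HXT7
IV	1154160	A	G	hom (Ref)->het	intergenic		HXT7
V	246512	A	T	hom (Ref)->het	intergenic		SAP1/CAJ1
V	246513	G	A	hom (Ref)->het	intergenic		SAP1/CAJ1
VII	96460	A	G	hom (Ref)->het	CDS	syn	MIG2
VII	674719	A	C	hom (Ref)->het	CDS	K 845 T	VAS1
VIII	71474	G	T	hom (Ref)->het	CDS	G 400 V	YHL017W
VIII	142574	C	G	hom (Ref)->het	CDS	E 329 Q	DED81
X	514538	G	T	hom (Ref)->hom (Alt)	CDS	V 162 F	NUP85
XI	248086	G	A	hom (Ref)->het	CDS	syn	YKL102C
XI	365899	A	C	hom (Ref)->het	CDS	syn	RGT1
XII	353829	A	T	hom (Ref)->het	CDS	S 3304 T	MDN1
XII	445330	C	A	hom (Ref)->het	intergenic		YLR152C/ACS2
XII	855305	C	T	hom (Ref)->het	CDS	S 36 L	YLR365W
XIII	136753	C	A	hom (Ref)->het	CDS	S 418 R	POB3
XIV	399951	C	A	hom (Ref)->het	CDS	G 196 V	TOM70
XIV	429367	A	C	hom (Ref)->het	CDS	K 545 Q	MET4
XIV	619219		+A	hom (Ref)->het	CDS	-169aa	SIS1
XV	172862	T	G	hom (Ref)->het	CDS	L 598 W	IRA2
XV	780679	T	G	hom (Ref)->hom (Alt)	intergenic		SNR17A/DFR1
XVI	113951	G	A	hom (Ref)->het	CDS	G 1767 D	FAS2
XVI	422593	C	G	hom (Ref)->het	CDS	S 549 *	MUK1
XVI	489680	C	A	hom (Ref)->het	CDS	R 562 L	SVL3
XVI	549443	C	T	hom (Ref)->het	CDS	P 320 S	AEP3
XVI	640448	A	C	hom (Ref)->het	CDS	Q 308 H	ARP7
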