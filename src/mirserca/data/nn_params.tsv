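kind	key	value
meta	version	mirserca-nn-1.0 (Turner-2004-style RNA/RNA, 37C)
init	duplex	4.1
stack	AA/UU	-0.93
stack	AU/UA	-1.10
stack	UA/AU	-1.33
stack	CU/GA	-2.08
stack	CA/GU	-2.11
stack	GU/CA	-2.24
stack	GA/CU	-2.35
stack	CG/GC	-2.36
stack	GG/CC	-3.26
stack	GC/CG	-3.42
stack	AG/UU	-0.55
stack	AU/UG	-1.36
stack	UG/AU	-1.27
stack	UU/AG	-1.00
stack	CG/GU	-1.41
stack	CU/GG	-2.11
stack	GG/CU	-1.53
stack	GU/CG	-2.51
stack	GG/UU	-0.50
stack	GU/UG	0.47
stack	UG/GU	0.30
loop	bulge_open	3.8
loop	bulge_ext	0.4
loop	internal_open	4.0
loop	internal_ext	0.3
hairpin	3	5.4
hairpin	4	5.6
hairpin	5	5.7
hairpin	6	5.4
hairpin	7	6.0
hairpin	8	5.5
hairpin	9	6.4
multibranch	offset	3.4
multibranch	per_branch	0.4
multibranch	per_unpaired	0.0
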