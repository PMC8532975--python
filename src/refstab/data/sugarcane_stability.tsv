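method	position	gene	score	sd
genorm	1	MCB1	0.15
genorm	2	LOG2	0.15
genorm	3	MOR1	0.35
genorm	4	TIC110	0.50
genorm	5	FAB2	0.60
genorm	6	VLN3	0.88
genorm	7	VHA	1.11
genorm	8	EF1a	1.39
genorm	9	ATPase	1.61
genorm	10	TUB6	1.95
normfinder	1	MOR1	0.09
normfinder	2	FAB2	0.10
normfinder	3	TIC110	0.10
normfinder	4	MCB1	0.26
normfinder	5	LOG2	0.41
normfinder	6	VLN3	0.80
normfinder	7	VHA	1.12
normfinder	8	EF1a	1.50
normfinder	9	ATPase	1.74
normfinder	10	TUB6	2.22
bestkeeper	1	FAB2	5.48	1.52
bestkeeper	2	VLN3	6.28	1.63
bestkeeper	3	TIC110	11.29	2.68
bestkeeper	4	MOR1	11.37	2.92
bestkeeper	5	MCB1	17.72	3.85
bestkeeper	6	VHA	18.71	4.16
bestkeeper	7	LOG2	19.28	4.46
bestkeeper	8	ATPase	20.32	4.30
bestkeeper	9	TUB6	20.38	4.32
bestkeeper	10	EF1a	21.69	5.35
consensus	1	FAB2	2.00
consensus	2	MOR1	2.00
consensus	3	MCB1	2.71
consensus	4	TIC110	3.00
consensus	5	LOG2	3.27
consensus	6	VLN3	3.91
consensus	7	VHA	6.32
consensus	8	EF1a	8.24
consensus	9	ATPase	8.32
consensus	10	TUB6	9.32
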