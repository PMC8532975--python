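gene	gene_id	accession	class	mean_rpkm	sd_rpkm	cv	amplicon_length	efficiency	r_squared
FAB2	Sspon.03G0028120	MW888380	novel	27.71	1.72	0.06	103	1.01	0.998
LOG2	Sspon.01G0006710	MW888381	novel	23.17	4.91	0.21	108	0.99	0.999
VHA	Sspon.08G0004380	MW888382	novel	22.25	4.52	0.20	106	1.02	0.998
MCB1	Sspon.01G0037150	MW888383	novel	21.73	4.16	0.19	111	0.99	0.995
ATPase	Sspon.06G0026890	MW888384	novel	21.16	4.83	0.23	111	0.97	0.996
ARM	Sspon.08G0021360	MW888385	novel	22.44	5.97	0.27	89	1.01	0.999
TIC110	Sspon.01G0020070	MW888386	novel	23.79	3.62	0.15	105	1.00	0.999
VLN3	Sspon.03G0026510	MW888387	novel	26.09	1.89	0.07	111	1.04	0.998
GET4	Sspon.03G0047080	MW888388	novel	24.52	7.18	0.29	98	0.99	0.995
MOR1	Sspon.03G0004010	MW888389	novel	25.75	3.11	0.12	101	0.99	0.998
EF1a	Sspon.07G0009240	MW888390	traditional	24.70	6.09	0.25	97	0.98	0.999
TUB6	Sspon.03G0016270	MW888391	traditional	21.23	4.59	0.22	92	1.04	0.998
GAPDH	Sspon.08G0001560	MW888392	traditional	19.76	5.71	0.29	94	1.00	0.996
UBC28	Sspon.08G0008230	MW888393	traditional	20.74	5.40	0.26	110	1.00	0.998
PP2A	Sspon.01G0003870	MW888394	novel	19.59	6.22	0.32	89	1.01	0.996
Expressed	Sspon.01G0058300	MW888395	novel	23.37	7.09	0.30	96	1.02	0.998
ACT7	Sspon.02G0047450	MW888396	traditional	19.13	10.30	0.54	99	0.99	0.996
ACT	Sspon.01G0006610	MW888397	traditional	19.09	9.58	0.50	100	1.01	0.996
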