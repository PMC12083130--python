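# Synthetic liver / whole-blood TPM profiles for the five disease-linked
# genes: THBD and F5 are well expressed in whole blood; F2, F9 and PROC are
# liver-dominant with sub-threshold, variable blood expression.
gene	BLD01	BLD02	BLD03	BLD04	BLD05	BLD06	BLD07	BLD08	LIV01	LIV02	LIV03	LIV04	LIV05	LIV06	LIV07	LIV08
THBD	10.4	12.1	13.8	9.6	11.2	14.5	12.9	10.9	5.1	6.3	4.8	7.2	5.9	6.8	5.4	6.1
F5	18.2	22.7	16.9	24.3	20.1	19.5	21.8	17.6	9.8	11.2	8.7	12.4	10.5	9.2	11.9	10.1
F2	0.21	0.08	0.55	0.14	0.32	0.05	0.47	0.18	412.5	389.2	450.8	398.4	421.7	405.3	437.9	416.2
F9	0.04	0.12	0.02	0.35	0.09	0.21	0.06	0.15	112.4	98.7	125.3	104.9	118.2	95.6	121.8	108.3
PROC	0.45	0.18	0.72	0.29	0.61	0.11	0.83	0.38	156.8	142.3	168.9	149.5	161.2	138.7	172.4	152.6
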