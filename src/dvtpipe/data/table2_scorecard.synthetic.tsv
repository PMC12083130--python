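# Synthetic reconstruction of the 28-gene seven-criterion annotation scorecard.
# The 14 genes with published totals (6/5/4) carry those totals; the remaining
# 14 genes score 3. Flag patterns honor the documented constraints: THBD and F5
# carry whole-blood eQTLs, F2/F9/PROC do not, and top-locus genes are flagged
# under top_gwas.
gene	top_gwas	missense_ld	blood_eqtl	go_bp	go_cc	go_mf	pid
IL6R	1	1	1	1	1	0	1
F5	1	1	1	1	0	1	0
ABO	1	1	1	0	1	1	0
F2	1	1	0	1	0	1	0
F9	1	1	0	1	1	0	0
F11	0	1	1	1	0	1	0
IL1RN	0	1	1	0	1	0	1
KLKB1	0	1	1	1	0	1	0
SH2B3	0	1	1	1	1	0	0
FGB	1	0	1	1	1	0	0
VWF	0	1	1	1	1	0	0
FGA	0	1	0	1	1	1	0
ADAMTS13	0	1	1	1	0	1	0
THBD	0	1	1	1	1	0	0
PLCG2	0	0	1	1	0	0	1
ST3GAL4	0	0	1	1	0	1	0
PROC	0	1	0	1	0	1	0
PLEK	0	0	1	1	1	0	0
ATP1B1	1	0	1	0	1	0	0
NME7	1	0	1	0	0	1	0
FGG	0	1	0	0	1	1	0
SLC44A2	0	1	1	0	1	0	0
PROCR	0	0	1	0	1	1	0
TSPAN15	1	0	1	0	1	0	0
ZFPM2	1	1	0	0	1	0	0
F8	0	1	0	0	1	1	0
SERPINC1	0	1	0	0	1	1	0
PLAT	0	0	1	0	1	1	0
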