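# Synthetic whole-blood eQTL flags for the five disease-linked genes:
# THBD and F5 carry significant whole-blood eQTLs, F2/F9/PROC do not.
gene	rsid	significant
THBD	rs1042580	1
F5	rs6025	1
F2	rs1799963	0
F9	rs6048	0
PROC	rs1799808	0
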