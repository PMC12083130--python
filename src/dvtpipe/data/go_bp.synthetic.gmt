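# Synthetic GO biological-process collection: the three
# coagulation/wound-healing terms overlap the 28-gene risk set in
# exactly 15 genes; the background terms carry generic filler genes.
GO:0050817	coagulation	ADAMTS13	F10	F11	F12	F13A1	F2	F5	F7	F9	FGA	FGB	GP1BA	ITGA2B	ITGB3	KLKB1	PLCG2	PLEK	PLG	PROC	PROS1	SERPINE1	SH2B3	ST3GAL4	THBD	VWF
GO:1903034	regulation of response to wounding	F2	F5	F9	FGA	FGB	GP9	KLKB1	PEAR1	PLEK	PLG	PROC	SERPINE1	TFPI	THBD	VWF
GO:0042060	wound healing	ADAMTS13	ENG	F11	F2	F5	F9	FGA	FGB	PDGFB	PLCG2	SH2B3	ST3GAL4	TGFB1	THBD	VWF
GO:9900000	ion transmembrane transport	ABO	BG0000	BG0001	BG0002	BG0003	BG0004	BG0005	BG0006	BG0007	BG0008	BG0009	BG0010	BG0011	BG0012	BG0013	BG0014	BG0015	BG0016	BG0017	BG0018	BG0019	BG0020	BG0021	BG0022	BG0023	BG0024	IL6R
GO:9900001	chromatin remodeling	ATP1B1	BG0100	BG0101	BG0102	BG0103	BG0104	BG0105	BG0106	BG0107	BG0108	BG0109	BG0110	BG0111	BG0112	BG0113	BG0114	BG0115	BG0116	BG0117	BG0118	BG0119	BG0120	BG0121	BG0122	BG0123	BG0124	IL1RN
GO:9900002	mRNA splicing	BG0200	BG0201	BG0202	BG0203	BG0204	BG0205	BG0206	BG0207	BG0208	BG0209	BG0210	BG0211	BG0212	BG0213	BG0214	BG0215	BG0216	BG0217	BG0218	BG0219	BG0220	BG0221	BG0222	BG0223	BG0224	FGG	NME7
GO:9900003	cilium assembly	BG0300	BG0301	BG0302	BG0303	BG0304	BG0305	BG0306	BG0307	BG0308	BG0309	BG0310	BG0311	BG0312	BG0313	BG0314	BG0315	BG0316	BG0317	BG0318	BG0319	BG0320	BG0321	BG0322	BG0323	BG0324	PROCR	SLC44A2
GO:9900004	lipid catabolic process	BG0400	BG0401	BG0402	BG0403	BG0404	BG0405	BG0406	BG0407	BG0408	BG0409	BG0410	BG0411	BG0412	BG0413	BG0414	BG0415	BG0416	BG0417	BG0418	BG0419	BG0420	BG0421	BG0422	BG0423	BG0424	TSPAN15	ZFPM2
GO:9900005	axon guidance	BG0500	BG0501	BG0502	BG0503	BG0504	BG0505	BG0506	BG0507	BG0508	BG0509	BG0510	BG0511	BG0512	BG0513	BG0514	BG0515	BG0516	BG0517	BG0518	BG0519	BG0520	BG0521	BG0522	BG0523	BG0524	F8	SERPINC1
GO:9900006	protein folding	BG0600	BG0601	BG0602	BG0603	BG0604	BG0605	BG0606	BG0607	BG0608	BG0609	BG0610	BG0611	BG0612	BG0613	BG0614	BG0615	BG0616	BG0617	BG0618	BG0619	BG0620	BG0621	BG0622	BG0623	BG0624	PLAT
GO:9900007	DNA repair	BG0700	BG0701	BG0702	BG0703	BG0704	BG0705	BG0706	BG0707	BG0708	BG0709	BG0710	BG0711	BG0712	BG0713	BG0714	BG0715	BG0716	BG0717	BG0718	BG0719	BG0720	BG0721	BG0722	BG0723	BG0724
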