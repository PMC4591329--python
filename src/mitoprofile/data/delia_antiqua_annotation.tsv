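Gene	Direction	Location	Size	Anticodon	Start	Stop	Intergenic
tRNA-Ile	F	1-66	66	31-33GAT
tRNA-Gln	R	64-132	69	100-102TTG			-3
tRNA-Met	F	136-204	69	166-168CAT			3
ND2	F	205-1221	1017		ATT	TAA	0
tRNA-Trp	F	1220-1287	68	1250-1252TCA			-2
tRNA-Cys	R	1280-1342	63	1311-1313GCA			-8
tRNA-Tyr	R	1353-1418	66	1385-1387GTA			10
COI	F	1416-2967	1552		ATCA	TAA	-3
tRNA-Leu(UUR)	F	2963-3028	66	2992-2994TAA			-5
COII	F	3037-3724	688		ATG	T	8
tRNA-Lys	F	3725-3795	71	3755-3757CTT			0
tRNA-Asp	F	3801-3868	68	3833-3835GTC			5
ATP8	F	3869-4033	165		ATT	TAA	0
ATP6	F	4027-4704	678		ATG	TAA	-7
COIII	F	4704-5492	789		ATG	TAA	-1
tRNA-Gly	F	5499-5563	65	5529-5531TCC			6
ND3	F	5561-5917	357		ATA	TAA	-3
tRNA-Ala	F	5922-5987	66	5951-5953TGC			4
tRNA-Arg	F	5987-6050	64	6016-6018TCG			-1
tRNA-Asn	F	6077-6142	66	6107-6109GTT			26
tRNA-Ser(AGN)	F	6142-6211	70	6168-6170GCT			-1
tRNA-Glu	F	6211-6278	68	6241-6243TTC			-1
tRNA-Phe	R	6297-6363	67	6329-6331GAA			18
ND5	R	6364-8083	1720		ATT	T	0
tRNA-His	R	8099-8165	67	8133-8135GTG			15
ND4	R	8166-9504	1339		ATG	TA	0
ND4L	R	9498-9794	297		ATG	TAA	-7
tRNA-Thr	F	9797-9861	65	9827-9829TGT			2
tRNA-Pro	R	9862-9927	66	9895-9897TGG			0
ND6	F	9930-10454	525		ATT	TAA	2
CytB	F	10454-11590	1137		ATG	TAA	-1
tRNA-Ser(UCN)	F	11593-11659	67	11623-11625TGA			2
ND1	R	11676-12614	939		ATA	TAA	16
tRNA-Leu(CUN)	R	12625-12689	65	12658-12660TAG			10
lrRNA	R	12690-14019	1330				0
tRNA-Val	R	14020-14091	72	14056-14058TAC			0
srRNA	R	14092-14875	784				0
control_region		14876-16141	1266				0
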