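Gene	Direction	Start	End	Size	Anticodon	StartCodon	StopCodon	IntergenicNucleotides
trnM	F	1	68	68	CAT	-	-	0
trnI	F	69	136	68	GAT	-	-	-3
trnQ	R	134	202	69	TTG	-	-	55
nad2	F	256	1273	1018	-	ATT	TAA	-2
trnW	F	1272	1341	70	TCA	-	-	2
trnC	R	1334	1397	64	GCA	-	-	0
trnY	R	1398	1461	64	GTA	-	-	14
cox1	F	1476	3004	1529	-	CCA	T	0
trnL2(UUR)	F	3005	3071	67	TAA	-	-	0
cox2	F	3072	3753	682	-	ATG	T	0
trnK	F	3754	3824	71	CTT	-	-	1
trnD	F	3826	3892	67	GTC	-	-	0
atp8	F	3893	4057	165	-	ATC	TAA	-7
atp6	F	4051	4728	678	-	ATG	TAA	-1
cox3	F	4728	5524	795	-	ATG	TAA	2
trnG	F	5527	5595	69	TCC	-	-	0
nad3	F	5596	5948	353	-	ATC	TAA	3
trnA	F	5952	6017	66	TGC	-	-	-1
trnR	F	6017	6081	65	TCG	-	-	0
trnN	F	6082	6148	67	GTT	-	-	-1
trnS1(AGN)	F	6148	6214	67	GCT	-	-	-1
trnE	F	6214	6279	66	TTC	-	-	-2
trnF	R	6278	6344	67	GAA	-	-	0
nad5	R	6345	8067	1723	-	ATA	T	0
trnH	R	8083	8139	57	GTG	-	-	24
nad4	R	8150	9537	1388	-	ATT	T	-1
nad4L	R	9537	9821	285	-	ATG	TAA	4
trnT	F	9826	9890	65	TGT	-	-	-1
trnP	R	9890	9955	66	TGG	-	-	1
nad6	F	9957	10488	532	-	ATG	TAA	-1
cytb	F	10488	11630	1143	-	ATG	TAA	-6
trnS2(UCN)	F	11625	11689	65	TGA	-	-	18
nad1	R	11708	12644	937	-	ATG	TAA	0
trnL1(CUN)	R	12645	12711	67	TAG	-	-	0
rrnL	R	12712	14049	1338	-	-	-	0
trnV	R	14050	14115	66	TAC	-	-	1
rrnS	R	14117	14895	778	-	-	-	1
AT_rich_region	F	14897	15247	351	-	-	-	-
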