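gene	direction	position	size	anticodon	start_codon	stop_codon
trnM	F	1-68	68	31-33 CAT	-	-
nad2	F	69-1085	1017	-	ATT	TAA
trnI	F	1217-1285	69	1247-1249 GAT	-	-
TRU		1295-4150	2856	-	-	-
trnW	F	4174-4245	72	4206-4208 TCA	-	-
cox1	F	4284-5825	1542	-	ATA	TAA
trnL(UUR)	F	5850-5920	71	5884-5886 TAA	-	-
cox2	F	5918-6601	684	-	ATG	TAA
trnK	F	6615-6685	71	6645-6647 CTT	-	-
trnD	F	6687-6760	74	6720-6722 GTC	-	-
atp8	F	6755-6925	171	-	ATA	TAG
atp6	F	6919-7602	684	-	ATG	TAA
cox3	F	7621-8406	786	-	ATG	TAG
trnG	F	8430-8500	69	8463-8465 TCC	-	-
nad3	F	8501-8854	354	-	ATT	TAG
trnA	F	8862-8935	74	8892-8894 TGC	-	-
trnN	F	8947-9011	65	8978-8980 GTT	-	-
trnR	F	9012-9078	67	9043-9045 TCG	-	-
trnS(AGN)	F	9125-9191	67	9150-9152 GCT	-	-
trnY	F	9199-9268	70	9228-9230 GTA	-	-
trnC	F	9274-9340	67	9303-9305 GCA	-	-
trnQ	F	9364-9432	69	9394-9396 TTG	-	-
trnE	R	9441-9526	86	9494-9496 TTC	-	-
trnF	R	9744-9812	69	9774-9776 GAA	-	-
nad5	R	9819-11570	1752	-	ATC	TAA
trnH	R	11568-11641	74	11597-11599 GTG	-	-
nad4	R	11641-12981	1341	-	ATG	TAA
nad4L	R	12981-13271	291	-	ATA	TAA
trnT	F	13275-13341	67	13308-13310 TGT	-	-
trnP	R	13342-13422	81	13388-13390 TGG	-	-
nad6	F	13425-13949	525	-	ATT	TAA
cytb	F	14033-15169	1137	-	ATG	TAG
trnS(UCN)	F	15277-15347	71	15307-15309 TGA	-	-
nad1	R	15450-16388	939	-	ATG	TAA
trnL(CUN)	R	16389-16454	66	6422-16424 TAG	-	-
rrnL	R	16455-17788	1334	-	-	-
trnV	R	17794-17862	69	17825-17827 TAC	-	-
rrnS	R	17878-18640	763	-	-	-
A+T-rich region		18641-20456	1816	-	-	-
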