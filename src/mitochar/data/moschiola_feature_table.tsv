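#accession=KY290452
#organism=Moschiola indica
#length=16444
#circular=true
gene	strand	start	end	size	anticodon
trnF	H	1	70	70	GAA
rrnS	H	71	1028	958
trnV	H	1029	1094	66	TAC
rrnL	H	1093	2668	1576
trnL2	H	2671	2744	74	TAA
nad1	H	2753	3694	942
trnI	H	3703	3771	69	GAT
trnQ	L	3769	3841	73	TTG
trnM	H	3844	3912	69	CAT
nad2	H	3913	4941	1029
trnW	H	4955	5021	67	TCA
trnA	L	5023	5090	68	TGC
trnN	L	5091	5163	73	GTT
trnC	L	5196	5264	69	GCA
trnY	L	5265	5331	67	GTA
cox1	H	5339	6877	1539
trnS2	L	6885	6953	69	TGA
trnD	H	6960	7026	67	GTC
cox2	H	7027	7707	681
trnK	H	7714	7779	66	TTT
atp8	H	7781	7978	198
atp6	H	7942	8616	675
cox3	H	8622	9404	783
trnG	H	9406	9474	69	TCC
nad3	H	9475	9819	345
trnR	H	9822	9889	68	TCG
nad4l	H	9890	10183	294
nad4	H	10180	11547	1368
trnH	H	11558	11628	71	GTG
trnS1	H	11629	11688	60	GCT
trnL1	H	11689	11758	70	TAG
nad5	H	11759	13561	1803
nad6	L	13569	14087	519
trnE	L	14091	14159	69	TTC
cob	H	14164	15297	1134
trnT	H	15304	15376	73	TGT
trnP	L	15376	15442	67	TGG
CR	H	15443	16332	890
trnF	H	16333	16402	70	GAA
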