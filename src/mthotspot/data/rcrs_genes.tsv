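# Human mtDNA (rCRS, NC_012920.1) gene map. 1-based, closed intervals.
# strand: H = heavy, L = light.
# name	start	end	strand
MT-TF	577	647	H
MT-RNR1	648	1601	H
MT-TV	1602	1670	H
MT-RNR2	1671	3229	H
MT-TL1	3230	3304	H
MT-ND1	3307	4262	H
MT-TI	4263	4331	H
MT-TQ	4329	4400	L
MT-TM	4402	4469	H
MT-ND2	4470	5511	H
MT-TW	5512	5579	H
MT-TA	5587	5655	L
MT-TN	5657	5729	L
MT-TC	5761	5826	L
MT-TY	5826	5891	L
MT-CO1	5904	7445	H
MT-TS1	7446	7514	L
MT-TD	7518	7585	H
MT-CO2	7586	8269	H
MT-TK	8295	8364	H
MT-ATP8	8366	8572	H
MT-ATP6	8527	9207	H
MT-CO3	9207	9990	H
MT-TG	9991	10058	H
MT-ND3	10059	10404	H
MT-TR	10405	10469	H
MT-ND4L	10470	10766	H
MT-ND4	10760	12137	H
MT-TH	12138	12206	H
MT-TS2	12207	12265	H
MT-TL2	12266	12336	H
MT-ND5	12337	14148	H
MT-ND6	14149	14673	L
MT-TE	14674	14742	L
MT-CYB	14747	15887	H
MT-TT	15888	15953	H
MT-TP	15956	16023	L
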