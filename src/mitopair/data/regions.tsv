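name	category	start	end	strand	frame_start
MT-DLOOP	control	16024	576	H	
MT-TF	tRNA	577	647	H	
MT-RNR1	rRNA	648	1601	H	
MT-TV	tRNA	1602	1670	H	
MT-RNR2	rRNA	1671	3229	H	
MT-TL1	tRNA	3230	3304	H	
MT-NC1	other_noncoding	3305	3306	H	
MT-ND1	protein_coding	3307	4262	H	3307
MT-TI	tRNA	4263	4331	H	
MT-TQ	tRNA	4329	4400	L	
MT-NC2	other_noncoding	4401	4401	H	
MT-TM	tRNA	4402	4469	H	
MT-ND2	protein_coding	4470	5511	H	4470
MT-TW	tRNA	5512	5579	H	
MT-NC3	other_noncoding	5580	5586	H	
MT-TA	tRNA	5587	5655	L	
MT-NC4	other_noncoding	5656	5656	H	
MT-TN	tRNA	5657	5729	L	
MT-NC5	other_noncoding	5730	5760	H	
MT-TC	tRNA	5761	5826	L	
MT-TY	tRNA	5826	5891	L	
MT-NC6	other_noncoding	5892	5903	H	
MT-CO1	protein_coding	5904	7445	H	5904
MT-TS1	tRNA	7446	7514	L	
MT-NC7	other_noncoding	7515	7517	H	
MT-TD	tRNA	7518	7585	H	
MT-CO2	protein_coding	7586	8269	H	7586
MT-NC8	other_noncoding	8270	8294	H	
MT-TK	tRNA	8295	8364	H	
MT-NC9	other_noncoding	8365	8365	H	
MT-ATP8	protein_coding	8366	8572	H	8366
MT-ATP6	protein_coding	8527	9207	H	8527
MT-CO3	protein_coding	9207	9990	H	9207
MT-TG	tRNA	9991	10058	H	
MT-ND3	protein_coding	10059	10404	H	10059
MT-TR	tRNA	10405	10469	H	
MT-ND4L	protein_coding	10470	10766	H	10470
MT-ND4	protein_coding	10760	12137	H	10760
MT-TH	tRNA	12138	12206	H	
MT-TS2	tRNA	12207	12265	H	
MT-TL2	tRNA	12266	12336	H	
MT-ND5	protein_coding	12337	14148	H	12337
MT-ND6	protein_coding	14149	14673	L	14673
MT-TE	tRNA	14674	14742	L	
MT-NC10	other_noncoding	14743	14746	H	
MT-CYB	protein_coding	14747	15887	H	14747
MT-TT	tRNA	15888	15953	H	
MT-NC11	other_noncoding	15954	15955	H	
MT-TP	tRNA	15956	16023	L	
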