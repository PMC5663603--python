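gene	position	end	ref	alt	kind	replacement	reported	aa_change_printed	conservation_printed
MT-DLOOP	71		G	A	substitution	G-A	Yes		
MT-DLOOP	72		T	C	substitution	T-C	Yes		
MT-DLOOP	74		T	G	substitution	T-G	Yes		
MT-DLOOP	94		G	A	substitution	G-A	Yes		
MT-DLOOP	157		T	C	substitution	T-C	No		
MT-DLOOP	294	341			deletion	294-341 Del	No		
MT-DLOOP	302		A	AC	insertion	A-AC	Yes		
MT-DLOOP	353		C	CC	insertion	C-CC	Yes		
MT-DLOOP	394		C	A	substitution	C-A	No		
MT-DLOOP	528		T	C	substitution	T-C	No		
MT-DLOOP	540		A	C	substitution	A-C	No		
MT-DLOOP	573		C	CCCCC	insertion	C-CCCCC	Yes		
MT-DLOOP	16368		T	C	substitution	T-C	Yes		
MT-DLOOP	16540		C	T	substitution	C-T	Yes		
MT-TF	617		G	A	substitution	G-A	No		
MT-RNR1	988		G	A	substitution	G-A	Yes		
MT-RNR1	1472		G	A	substitution	G-A	Yes		
MT-RNR2	2623		A	G	substitution	A-G	Yes		
MT-ND1	3710		C	T	substitution	C-T	Yes	Ala-Val	16/17
MT-ND1	3877		T	C	substitution	T-C	No	Ala-Pro	17/17
MT-ND2	4963		G	A	substitution	G-A	No	Gly-Asp	17/17
MT-ND2	5112		G	A	substitution	G-A	Yes	Ala-Thr	5/17
MT-TN	5705		A	G	substitution	A-G	Yes		
MT-CO1	6582		G	A	substitution	G-A	No	Asp-Asn	17/17
MT-CO1	7347		G	A	substitution	G-A	Yes	Val-Ile	16/17
MT-ATP8	8369		C	G	substitution	C-G	Yes	Pro-Ser	17/17
MT-ATP6	8628		C	CC	insertion	C-CC	No	frameshift (stop)	12/17
MT-CO3	9253		G	A	substitution	G-A	Yes	Trp-stop	17/17
MT-CO3	9670		A	G	substitution	A-G	Yes	Asn-Ser	13/17
MT-ND3	10365		G	A	substitution	G-A	Yes	Ala-Thr	13/17
MT-ND4L	10689		G	A	substitution	G-A	Yes	Gly-Ser	16/17
MT-ND4	11226		G	A	substitution	G-A	No	Gly-Asp	17/17
MT-ND4	11929		T	C	substitution	T-C	Yes	Syn	
MT-TS2	12209		G	A	substitution	G-A	Yes		
MT-ND5	12634		A	G	substitution	A-G	Yes	Ile-Val	14/17
MT-ND5	12711		A	G	substitution	A-G	Yes	Syn	17/17
MT-ND5	12954		T	C	substitution	T-C	Yes	Syn	17/17
MT-ND5	13063		G	A	substitution	G-A	Yes	Val-Ile	17/17
MT-ND5	13267		G	T	substitution	G-T	No	Gly-Trp	17/17
MT-ND5	13475		T		deletion	T-Del	No	frameshift (stop)	17/17
MT-ND5	13603		A	G	substitution	A-G	No	Ser-Gly	17/17
MT-ND5	13676		A	G	substitution	A-G	Yes	Asn-Ser	15/17
MT-ND5	13718		G	A	substitution	G-A	Yes	Ser-Asn	17/17
MT-CYB	14984		C	CA	insertion	C-CA	No	frameshift (stop)	15/17
MT-CYB	15860		A	G	substitution	A-G	Yes	Ile-Val	12/17
MT-TP	16017		T	C	substitution	T-C	Yes		
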