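haplogroup	macro	position	ref	alt
D	M	489	T	C
D	M	10400	C	T
D	M	14783	T	C
D	M	15043	G	A
D	M	4883	C	T
D	M	5178	C	A
D	M	16362	T	C
G	M	489	T	C
G	M	10400	C	T
G	M	14783	T	C
G	M	15043	G	A
G	M	4833	A	G
G	M	16274	G	A
M7	M	489	T	C
M7	M	10400	C	T
M7	M	14783	T	C
M7	M	15043	G	A
M7	M	6455	C	T
M7	M	9824	T	C
M7	M	16297	T	C
M8	M	489	T	C
M8	M	10400	C	T
M8	M	14783	T	C
M8	M	15043	G	A
M8	M	4715	A	G
M8	M	7196	C	A
M8	M	8584	G	A
M8	M	16298	T	C
M12	M	489	T	C
M12	M	10400	C	T
M12	M	14783	T	C
M12	M	15043	G	A
M12	M	14727	T	A
M12	M	16234	C	T
A	N	663	A	G
A	N	1736	A	G
A	N	4824	A	G
A	N	8794	C	T
A	N	16290	C	T
A	N	16319	G	A
N9	N	5417	G	A
N9	N	16257	C	A
N9	N	16261	C	T
R9	N	3970	C	T
R9	N	13928	G	C
R9	N	16304	T	C
R11	N	1095	T	C
R11	N	16189	T	C
R11	N	16311	T	C
B	N	499	G	A
B	N	827	A	G
B	N	16189	T	C
B	N	16217	T	C
H2	N	1438	A	G
H2	N	4769	A	G
H2	N	8860	A	G
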