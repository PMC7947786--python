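# Reciprocal-mutagenesis position set for the depupylase Dop vs the Pup-ligase PafA.
# One row per alignment position selected for mutagenesis in the M. smegmatis Dop
# background. Columns give, per family, the wild-type residue and its number in the
# M. smegmatis enzyme and in the structure-bearing ortholog (A. cellulolyticus Dop /
# C. glutamicum PafA), plus the 1-9 conservation grade of the position in that family.
# kind: substitution | deletion (the ~37-residue Dop-loop) | insertion (PafA-only
#       residue) | deletion_covered (substituted implicitly by the loop deletion)
# region: alpha_loop rows form the alpha-loop block; supporting rows carry a segment
#         label (1-5) grouping them for the combinatorial library.
no	kind	region	segment	dop_msm_res	dop_msm_pos	dop_ref_res	dop_ref_pos	dop_grade	pafa_msm_res	pafa_msm_pos	pafa_ref_res	pafa_ref_pos	pafa_grade
3	substitution	supporting	1	S	27	S	27	9	A	30	A	37	9
4	substitution	supporting	1	V	31	V	31	8	F	34	F	41	9
loop	deletion	dop_loop		A	43	V	79
5	deletion_covered	supporting		A	81	L	80	7	S	43	S	50	9
6	deletion_covered	supporting		A	82	A	81	8	S	44	S	51	9
7	substitution	supporting	2	I	85	I	84	8	F	47	F	54	9
9	substitution	supporting	3	V	94	V	93	9	L	56	L	63	9
10	insertion	supporting	3		95				V	58	V	65	9
11	substitution	supporting	3	H	96	H	95	9	G	59	G	66	9
12	substitution	supporting	3	A	97	A	96	9	S	60	S	67	9
13	substitution	supporting	4	S	102	S	101	9	A	65	A	72	9
14	substitution	supporting	4	A	103	T	102	7	T	66	T	73	9
15	substitution	supporting	4	P	104	P	103	9	A	67	A	74	9
25	substitution	alpha_loop		Y	209	F	208	8	H	174	H	188	8
26	substitution	alpha_loop		E	211	E	210	9	W	176	W	190	7
27	substitution	alpha_loop		V	212	V	211	8	E	177	E	191	9
28	substitution	alpha_loop		E	213	E	212	8	G	178	G	192	7
29	substitution	alpha_loop		G	215	G	214	9	S	180	S	194	9
30	substitution	alpha_loop		L	216	L	215	9	S	181	S	195	9
31	substitution	alpha_loop		E	217	E	216	9	A	182	A	196	9
32	substitution	alpha_loop		L	220	L	219	8	R	185	R	199	9
33	substitution	alpha_loop		K	221	K	220	8	S	186	S	200	9
46	substitution	supporting	5	S	450	S	452	8	D	418	D	439	9
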