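# Curated feature table for the flax (Linum usitatissimum) PME/PMEI gene
# families (CDC Bethune whole-genome assembly v1.0). One row per gene.
# PMEIs: mature-protein size/pI, signal-peptide and transmembrane flags,
# conserved-residue counts in six curated residue groups (cons_g1..cons_g6,
# group maxima 11/5/4/3/3/4; 30 of the 33 panel residues are encodable from
# this table), the residue observed at the N-terminal orientation position
# (orientation_aa), and transcription evidence.
gene	aa	kda	pi	sp	tm	cons_g1	cons_g2	cons_g3	cons_g4	cons_g5	cons_g6	orientation_aa	expressed
LuPMEI1	155	16.1	6.8	+	-	10	4	4	1	0	4	N	+
LuPMEI2	174	18.9	8.6	-	-	8	2	2	0	2	2	A	-
LuPMEI3	162	17.9	6.1	+	-	6	3	2	1	2	4	G	+
LuPMEI4	113	12.6	4.9	-	-	2	1	4	1	2	2	-	-
LuPMEI5	159	17	4.9	+	-	9	5	4	3	1	4	P	+
LuPMEI6	177	18.7	8.8	+	+	11	5	4	2	1	4	A	+
LuPMEI7	155	16.8	5.6	+	+	11	4	3	1	3	4	A	-
LuPMEI8	167	17.8	5.3	-	+	7	2	3	2	1	4	T	-
LuPMEI9	192	21.5	10	+	+	5	4	4	1	1	4	T	-
LuPMEI10	199	21.2	5.1	+	-	7	2	4	0	0	4	P	-
LuPMEI11	296	33.7	4.7	-	-	6	3	4	1	2	4	H	-
LuPMEI12	155	16.7	8.4	+	-	8	4	2	1	0	3	A	+
LuPMEI13	160	16.8	8.3	+	-	11	4	2	1	0	4	S	+
LuPMEI14	159	17.4	5.1	+	-	11	3	4	2	1	4	S	+
LuPMEI15	159	17.3	5.1	+	-	11	3	4	2	1	4	S	+
LuPMEI16	198	21.3	5.1	+	-	7	5	4	3	1	4	I	+
LuPMEI17	187	20.3	4.5	+	+	8	4	3	1	2	4	A	+
LuPMEI18	181	19.5	8.3	+	-	8	3	3	3	1	4	A	+
LuPMEI19	159	17	5	+	-	9	5	4	3	1	4	P	+
LuPMEI20	239	26	5.6	-	+	9	4	4	2	1	4	S	+
LuPMEI21	161	17.2	7.9	+	-	11	3	4	1	2	4	A	-
LuPMEI22	483	55.4	4.6	+	-	5	3	4	1	2	4	P	+
LuPMEI23	198	20.8	4.9	+	-	6	3	3	1	1	4	P	+
LuPMEI24	180	19.6	8.9	+	-	9	3	3	0	0	4	P	+
LuPMEI25	172	18.6	4.9	+	-	11	5	3	3	1	4	K	+
LuPMEI26	154	16.2	5.5	+	-	10	4	2	1	1	4	A	+
LuPMEI27	149	16.4	4.7	+	-	10	3	4	1	2	4	N	+
LuPMEI28	166	17.1	8.3	+	-	11	4	2	1	0	4	S	+
LuPMEI29	149	16.7	4.8	+	-	10	2	4	1	1	4	N	+
LuPMEI30	149	16.4	4.6	+	+	10	2	4	1	0	4	T	+
LuPMEI31	165	17.8	5.5	+	-	11	4	2	1	1	3	K	-
LuPMEI32	155	16.5	8.4	+	+	10	4	3	1	0	4	T	+
LuPMEI33	152	15.9	5.1	+	-	9	4	3	1	2	4	A	+
LuPMEI34	152	16.2	4.7	+	+	11	4	4	2	2	4	A	+
LuPMEI35	154	16.1	4.6	+	-	10	4	4	2	2	4	A	+
LuPMEI36	152	16.3	4.7	+	-	11	5	4	3	2	4	A	+
LuPMEI37	167	17.9	5.4	-	-	8	4	4	2	1	4	P	+
LuPMEI38	163	17.8	7.8	+	-	9	5	3	1	2	4	P	+
LuPMEI39	158	17.4	4.5	-	-	10	5	2	3	1	4	K	+
LuPMEI40	164	17.6	5.7	+	+	9	5	3	2	2	4	A	+
LuPMEI41	151	16.1	5.3	+	-	11	5	2	1	2	4	M	+
LuPMEI42	159	17.2	6.1	+	-	10	3	4	1	1	4	S	+
LuPMEI43	181	19.6	9.5	+	-	7	4	4	1	1	4	I	+
LuPMEI44	187	19.9	6.8	+	+	7	5	4	2	1	4	I	+
LuPMEI45	159	17.3	6.5	+	-	7	3	4	3	1	4	I	+
LuPMEI46	389	45	5.1	-	-	5	3	4	1	2	4	P	+
LuPMEI47	188	20.2	8.4	+	-	7	3	4	0	1	4	P	+
LuPMEI48	193	21.2	7.7	+	+	7	3	4	1	0	4	P	+
LuPMEI49	197	21.5	6.9	+	+	8	3	4	1	0	4	P	-
LuPMEI50	467	50.6	6.5	-	-	7	4	3	1	3	4	A	+
LuPMEI51	368	37.4	4.3	+	+	8	4	2	1	2	4	P	+
LuPMEI52	65	7.3	4.5	-	-	5	1	1	0	1	1	-	+
LuPMEI53	161	17.8	9	+	+	7	5	4	3	1	4	I	+
LuPMEI54	175	18.7	6.1	+	-	7	5	4	3	1	4	I	+
LuPMEI55	141	15.3	5.9	-	-	4	1	4	2	1	3	-	+
LuPMEI56	167	18.8	8.3	+	-	7	4	3	1	2	4	D	+
LuPMEI57	154	16	6.4	+	+	9	4	4	2	0	4	N	+
LuPMEI58	195	21.1	5.2	+	-	7	5	4	3	1	4	I	+
LuPMEI59	173	18.9	4.5	+	-	10	5	2	3	1	4	K	+
LuPMEI60	195	21.7	9.9	+	-	6	4	4	1	1	4	T	+
LuPMEI61	468	51.7	8.7	-	-	7	4	3	3	1	3	G	+
LuPMEI62	118	13.2	6.9	-	+	4	1	3	2	3	2	-	-
LuPMEI63	170	18.3	5.9	+	-	7	5	4	2	2	4	V	+
LuPMEI64	177	19.1	10	+	-	7	4	4	3	1	4	I	+
LuPMEI65	180	19.1	5.3	+	-	6	5	4	3	1	4	I	+
LuPMEI66	160	17.8	7.8	+	-	7	3	4	0	2	4	T	+
LuPMEI67	174	18.8	4.6	+	-	11	5	4	3	1	4	K	+
LuPMEI68	177	19	5.5	+	-	7	5	4	3	2	4	V	+
LuPMEI69	179	19.3	9.2	+	-	7	5	4	3	2	4	I	+
LuPMEI70	177	19.2	10.1	+	-	7	4	4	3	1	4	I	+
LuPMEI71	183	19.6	5.7	+	-	6	5	4	3	1	4	I	+
LuPMEI72	183	20	9.4	+	-	7	5	4	1	1	4	I	+
LuPMEI73	212	22.6	7.7	+	-	7	5	4	2	1	4	I	+
LuPMEI74	159	17.4	5.5	+	-	6	3	4	3	1	3	I	+
LuPMEI75	170	19.1	9	+	-	7	5	3	1	2	4	D	+
LuPMEI76	228	25	9	+	-	9	3	2	0	0	4	P	+
LuPMEI77	220	23	4.6	-	-	9	3	3	1	1	4	P	+
LuPMEI78	163	17.7	5.7	+	-	11	4	2	1	1	4	K	+
LuPMEI79	155	16.6	6.9	+	+	10	4	3	1	0	4	T	+
LuPMEI80	229	24.9	5.7	+	-	7	4	3	2	2	4	A	-
LuPMEI81	184	19.3	4.8	-	-	5	2	4	2	1	3	P	+
LuPMEI82	334	34.4	4.4	+	+	8	4	2	1	2	4	P	+
LuPMEI83	249	26.9	4.7	+	-	7	4	3	1	2	4	A	+
LuPMEI84	193	20.5	4.7	+	-	7	5	4	2	1	4	V	+
LuPMEI85	156	16.9	8.4	+	-	8	3	3	0	0	4	R	+
LuPMEI86	150	16.2	9.2	+	+	10	2	4	0	1	4	A	+
LuPMEI87	162	17.7	9	+	-	7	5	4	3	1	4	I	+
LuPMEI88	172	18.3	5.4	+	+	7	5	4	3	1	4	I	+
LuPMEI89	155	16.6	8.8	+	+	10	2	4	0	1	4	A	+
LuPMEI90	188	19.9	5.7	-	-	6	3	3	2	1	2	P	+
LuPMEI91	327	36.6	9.2	-	+	9	4	3	2	3	4	T	+
LuPMEI92	162	17.9	7.8	+	-	6	3	2	1	2	4	G	+
LuPMEI93	156	16.5	4.4	+	+	11	5	4	2	2	4	G	+
LuPMEI94	331	35.9	6.3	-	+	9	4	4	2	1	4	S	+
LuPMEI95	157	17.3	5.3	-	-	8	4	3	1	2	3	P	+
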