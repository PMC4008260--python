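# Curated feature table for the flax (Linum usitatissimum) PME/PMEI gene
# families (CDC Bethune whole-genome assembly v1.0). One row per gene.
# Type-2 PMEs (no pro-region): mature-protein size/pI, signal-peptide and
# transmembrane flags, conserved-residue counts, transcription evidence.
gene	aa	kda	pi	sp	tm	aromatic	stabilizer	catalytic	expressed
LuPME2	192	21	4.8	+	-	1	1	2	-
LuPME4	305	34.4	6.5	-	-	5	1	3	-
LuPME10	348	38.2	8.4	+	+	4	2	3	+
LuPME12	223	23.1	8.7	-	-	2	0	2	+
LuPME15	267	29.9	5.7	-	-	3	1	2	+
LuPME16	329	37.1	9.4	+	-	5	1	3	+
LuPME20	252	27.6	8.9	-	-	5	1	3	-
LuPME21	352	39.1	8.5	-	+	6	2	3	+
LuPME24	414	45.4	8.3	-	+	5	2	3	+
LuPME25	319	34.7	8.5	+	-	4	1	3	+
LuPME26	322	35.4	9.5	+	-	5	1	3	+
LuPME27	363	39.7	8.9	+	+	6	2	3	+
LuPME28	74	8.5	11.2	-	-	0	0	0	+
LuPME29	356	39.3	9.1	+	+	6	2	3	+
LuPME33	219	24.8	4.9	-	-	5	0	2	-
LuPME34	317	35.5	7.7	-	-	6	2	3	+
LuPME35	145	15.9	9.1	-	-	3	0	1	-
LuPME39	348	38.8	7.8	+	+	4	2	3	+
LuPME40	316	35.8	9	+	-	5	1	3	+
LuPME41	340	37.3	6.3	+	-	3	2	3	+
LuPME42	216	24.4	8.4	-	-	1	0	0	-
LuPME48	379	40.2	8.7	-	-	3	0	2	+
LuPME52	336	37.6	6	-	-	6	1	3	+
LuPME55	330	36.2	9	+	-	3	1	3	+
LuPME57	260	28.8	6.8	-	-	2	1	3	-
LuPME58	123	14.4	9.4	-	-	3	0	1	+
LuPME59	318	35.6	7.7	-	-	6	2	3	+
LuPME60	325	35.2	8.4	+	+	4	1	3	-
LuPME61	302	31.9	9.4	-	-	6	2	3	+
LuPME67	418	45.9	5.6	-	+	4	2	3	+
LuPME68	316	35.1	9.4	-	-	6	2	3	+
LuPME69	220	24.5	7.9	-	-	5	2	3	+
LuPME77	318	35.2	7.7	+	-	5	1	3	+
LuPME87	348	38.5	7.3	-	-	3	2	3	-
LuPME88	140	15.5	8.9	-	-	1	0	0	-
LuPME89	311	33.6	5.2	-	-	3	2	2	+
LuPME90	339	37.1	6.3	+	-	3	2	3	+
LuPME94	332	37.6	8.5	+	-	3	1	2	+
LuPME98	354	40.1	8.1	+	-	5	1	3	-
LuPME100	289	32.3	7	-	-	1	0	2	-
LuPME101	318	36.2	7.2	+	-	4	1	2	+
LuPME102	317	35.1	5.5	-	-	5	2	3	+
LuPME103	359	39.8	8.9	+	-	6	2	3	+
LuPME104	349	38.4	9.3	-	-	4	1	3	-
LuPME105	343	37.6	9.1	-	-	6	2	3	+
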