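# Curated feature table for the flax (Linum usitatissimum) PME/PMEI gene
# families (CDC Bethune whole-genome assembly v1.0). One row per gene.
# Type-1 PMEs: mature-protein size/pI, pro-region cleavage motifs (BM1/BM2
# tetrapeptides with 1-based start positions), signal-peptide (sp) and
# transmembrane (tm) flags, conserved-residue counts against the tomato PME
# panel (aromatic of 6, stabilizer of 2, catalytic of 3), and whether any
# experimental transcription evidence exists (expressed).
gene	aa	kda	pi	bm1	bm2	positions	sp	tm	aromatic	stabilizer	catalytic	expressed
LuPME1	333	34.9	8.82	RKLL	RKLL	203-223	+	-	6	2	3	+
LuPME3	320	34.4	9.77		RRLL	235	+	+	6	2	3	+
LuPME5	319	34.6	9.53		RRLL	234	-	+	6	2	3	+
LuPME6	322	35.5	7.18	RKLL	RRVL	202-217	+	-	5	2	3	+
LuPME7	322	35	6.6	RKVA	RRLL	235-259	+	-	6	2	3	+
LuPME8	364	40.1	8.66	RKLL	RRLL	263-286	-	+	6	2	3	+
LuPME9	322	35.6	9.6	RRLL	RKLL	224-242	+	+	5	2	3	+
LuPME11	593	64.1	8.46				-	+	6	2	3	+
LuPME13	323	35.3	10		RRLL	137	-	-	6	2	3	-
LuPME14	321	35.3	9.47	RRLL	RKLL	226-248	-	+	5	2	3	+
LuPME17	322	35.4	8.89	RRLW	RRLL	197-221	+	+	6	2	3	+
LuPME18	393	43.1	8.39	RKLR		207	+	-	5	2	3	+
LuPME19	331	36.4	8.33	RKLL	RKLL	163-187	-	-	6	2	3	+
LuPME22	324	35.8	8.8		RRKL	613	-	-	6	2	3	+
LuPME23	334	36.8	7.06				+	+	6	2	3	-
LuPME30	291	32	9	RRLW	RRLL	232-258	-	+	5	1	2	+
LuPME31	323	35.6	8.21	RKLK		195	+	+	6	2	3	+
LuPME32	386	41.2	9.51				-	+	1	0	0	+
LuPME36	534	58.9	8.97				+	-	6	2	3	+
LuPME37	398	45.2	5.93	RRLL	RRLL	246-283	-	+	6	2	3	+
LuPME38	473	52.2	6.41				+	-	6	2	3	+
LuPME43	297	32.6	9.49	RRML	RKLL	241-273	-	+	6	2	3	+
LuPME44	414	46	7.74		RKLL	103	-	-	6	2	3	+
LuPME45	318	33.5	8.6		RELL	195	+	+	5	2	3	+
LuPME46	324	35.8	9.67	RRLL	RRLL	263-292	-	+	6	2	3	+
LuPME47	326	35.6	9.17	RRML	RKLL	241-273	-	+	6	2	3	+
LuPME49	525	58.4	9.29				+	-	6	2	3	+
LuPME50	427	46	9.47				+	-	4	1	1	+
LuPME51	359	39.8	5.21	RRLL		406	-	-	2	1	0	-
LuPME53	322	35.4	9.05	RRLL	RRLL	213-239	-	-	5	2	3	+
LuPME54	533	58.9	9.79	RRLL	RRLL	253-281	-	+	6	2	3	+
LuPME56	322	35.6	9.61	RRLL	RKLL	222-240	+	+	5	2	3	+
LuPME62	334	36	9.94		RRLL	217	+	+	6	2	3	-
LuPME63	518	57.6	9.54				+	+	6	2	3	-
LuPME64	322	35.9	10.32		RKVL	358	-	-	6	2	3	-
LuPME65	319	34.3	9.01		RRLL	187	-	-	6	2	3	-
LuPME66	348	38.9	5.87	RRLL	RRML	265-289	-	+	5	2	3	+
LuPME70	387	42.7	7.71	RKLR		204	+	-	6	2	3	+
LuPME71	529	58.6	5.92				+	-	6	2	3	+
LuPME72	407	46.1	5.57	RRLL	RRLL	318-350	-	-	6	2	3	+
LuPME73	223	24.6	9.03		RKLL	250	+	-	6	2	3	+
LuPME74	526	58.6	9.29				+	-	6	2	3	+
LuPME75	327	36.1	9.92		GRLL		+	+	6	2	3	-
LuPME76	335	36.8	8.76		RRLL	224	+	-	6	1	3	-
LuPME78	400	45.4	6.12	RRLL	RRLL	227-258	+	+	6	2	3	+
LuPME79	536	59	9.04				+	-	6	2	3	+
LuPME80	327	36.1	9.68				+	+	6	2	3	-
LuPME81	327	36	9.13		GRLL		+	-	6	2	3	+
LuPME82	334	37.2	9.49	RRLL	REYL	242-253	-	+	6	2	3	-
LuPME83	322	35.4	8.95	RRLL	RKLL	237-260	-	+	5	2	3	+
LuPME84	547	60.7	5.25				-	+	6	2	3	+
LuPME85	318	33.4	7.84		RKLL	203	+	+	5	2	3	+
LuPME86	330	37	9.52	RRLL	REYL	241-252	-	+	5	2	3	-
LuPME91	321	35.2	9	RKLL	RRLL	274-301	-	+	6	2	3	+
LuPME92	331	36.3	7.82		RRLL	267	+	+	6	2	3	+
LuPME93	347	37.7	5.16	RRLL	RRFL	246-272	-	+	3	2	3	+
LuPME95	323	34.8	9.47		RRLL	214	+	+	6	2	3	-
LuPME96	327	36.6	10.22		RKVL	154	-	-	6	2	3	-
LuPME97	402	45.1	10.48		RRVL	228	+	+	6	2	3	-
LuPME99	324	36.2	8.24	RRLL	RRML	277-301	-	+	5	2	3	+
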