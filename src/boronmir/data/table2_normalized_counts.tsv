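# RPKM-normalized per-precursor read counts in the four barley libraries
# (root/leaf x 50 uM control / 1000 uM boron). No #totals line: values are
# already normalized, so they are consumed as-is by the fold-change caller.
precursor_id	root_control	root_treated	leaf_control	leaf_treated
hvu-miR156	146	232	28	81
hvu-miR156a/miR156b/miR156r	874	848	199	139
hvu-mir156c	22	21	0	0
hvu-mir157	46	25	87	43
hvu-miR159	746	886	196	339
hvu-miR160	211	236	4	4
hvu-miR160o	525	473	190	283
hvu-miR164a	120	177	28	20
hvu-miR165	104	221	58	78
hvu-miR166c	80	146	44	76
hvu-miR168	634	890	125	166
hvu-miR169	1711	937	192	263
hvu-miR169c	3	3	3	19
hvu-miR171	1450	1289	477	1090
hvu-miR171a	264	205	26	71
hvu-miR172	1473	699	149	651
hvu-miR319c	31	26	5	4
hvu-miR319/miR319a	171	211	0	0
hvu-miR397	58	51	15	2
hvu-miR399	124	35	31	94
hvu-miR408	0	0	130	8
hvu-miR444a	562	926	4	21
hvu-miR444b	83	26	14	21
hvu-miR444c	236	151	36	91
hvu-miR1120	869	1261	468	797
hvu-miR1121	2237	2115	31	11
hvu-miR1122	170	277	156	113
hvu-miR2004	4	9	118	77
hvu-miR2014	26	22	5	2
hvu-miR2021	9	22	18	6
hvu-miR2023a	38	70	34	69
hvu-miR2024a	83	26	14	21
hvu-miR2906	80	85	120	106
hvu-miR5048	1019	1169	217	218
hvu-miR5049	37	43	26	7
hvu-miR5051	35	73	27	35
hvu-miR5053	277	733	126	20
hvu-miR5064	248	250	116	159
hvu-miR5066	8	16	30	4
hvu-miR5141	993	1247	1199	175
hvu-miR5052	0	0	8	0
hvu-miR5180a/miR5180b	278	240	25	2
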