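# Published per-tissue boron-response calls for the 25 responsive miRNAs.
# direction: up / down / unchanged / not_detected as printed; fold is the
# printed integer fold (empty when no fold is printed). known_inconsistency=1
# marks the one row whose printed direction contradicts its own counts
# (miR2024a root: 83 -> 26 printed "up-regulated"); the caller reports down.
call_id	leaf_control	leaf_treated	leaf_direction	leaf_fold	root_control	root_treated	root_direction	root_fold	known_inconsistency
miR156	28	81	up	2	146	232	unchanged		0
miR156d	87	43	down	2	46	25	unchanged		0
miR165	58	78	unchanged		104	221	up	2	0
miR169c	3	19	up	6	3	3	unchanged		0
miR171	477	1090	up	2	1450	1289	unchanged		0
miR171a	26	71	up	2	264	205	unchanged		0
miR172	149	651	up	4	1473	699	down	2	0
miR397	15	2	down	7	58	51	unchanged		0
miR399	31	94	up	3	124	35	down	3	0
miR408	130	8	down	16	0	0	not_detected		0
miR444a	4	21	up	5	562	926	unchanged		0
miR444b	14	21	unchanged		83	26	down	3	0
miR444c	36	91	up	2	236	151	unchanged		0
miR1121	31	11	down	2	2237	2115	unchanged		0
miR2004	118	77	unchanged		4	9	up	2	0
miR2014	5	2	down	2	26	22	unchanged		0
miR2021	18	6	down	3	9	22	up	2	0
miR2023a	34	69	up	2	38	70	unchanged		0
miR2024a	14	21	unchanged		83	26	up	3	1
miR5049	26	7	down	3	37	43	unchanged		0
miR5051	27	35	unchanged		35	73	up	2	0
miR5053	126	20	down	6	277	733	up	2	0
miR5066	30	4	down	7	8	16	up	2	0
miR5141	1199	175	down	6	993	1247	unchanged		0
miR5180a/miR5180b	25	2	down	12	278	240	unchanged		0
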