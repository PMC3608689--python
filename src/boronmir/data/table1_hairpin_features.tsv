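# Barley pre-miRNA features as published: mature sequence, mature length (LM),
# precursor length (LP), MFEI (printed, 2-decimal), GC%, minimum folding energy dG (kcal/mol).
# mfei_consistent = 1 when the printed MFEI equals trunc2(((|dG|/LP)*100)/GC%);
# the single 0 row (hvu-mir-397) does not reproduce from its own printed triple
# (0.98 printed vs 0.84 computed; GC% 57 instead of 67 would give 0.98).
name	mature_seq	lm	lp	mfei	gc_percent	dg	mfei_consistent
hvu-mir-156	UGACAGAAGAGAGAGAGCAC	20	178	0.71	65.0	-83.20	1
hvu-mir-157	UUGACAGAAGAGAGUGAGCAC	21	85	1.12	55.0	-52.40	1
hvu-mir-159	UUUGGAUUGAAGGGAGCUCUG	21	178	0.93	52.0	-86.30	1
hvu-mir-160	UGCCUGGCUCCCUGUAUGCCA	21	98	0.95	60.0	-56.00	1
hvu-mir-164	UGGAGAAGCAGGGCACUUGCU	21	75	0.74	61.0	-34.10	1
hvu-mir-165	CCGCGACUGCCCCAUCCUCA	20	100	0.51	62.0	-31.90	1
hvu-mir-166	CCGGACCAGGCUUCAUUCCCA	21	61	0.34	59.0	-12.50	1
hvu-mir-168	GAUCCCGCCUUGCACCAAGUGAAU	24	106	0.81	75.0	-64.40	1
hvu-mir-169	AAGCCAAGGAUGAGUUGCCUG	21	83	0.80	45.0	-30.10	1
hvu-mir-171	UGAUUGAGCCGUGCCAAUAUC	21	137	0.97	55.0	-73.20	1
hvu-mir-172c	AGGAUCUUGAUGAUGCUGCUG	21	54	0.60	41.0	-13.40	1
hvu-mir-319a	UUGGACUGAAGGGAGCUCCC	20	186	0.90	52.0	-87.70	1
hvu-mir-319c	UUGGAAUGAAGGGAGCUCAA	20	78	0.55	45.0	-19.60	1
hvu-mir-397	CCGUUGAGUGCAGCGUUGAUG	21	133	0.98	67.0	-74.90	0
hvu-mir-399	UGCCAAAGGAGAUUUGCCCCG	21	113	0.65	46.0	-34.20	1
hvu-mir-408	CUGCACUGCCUCUUCCCUGGC	21	149	0.80	56.0	-67.50	1
hvu-mir-444b	UGCAGUUGCUGUCUCAAGCUU	21	121	1.01	45.0	-55.20	1
hvu-mir-1120	ACAUUCUUAUAUUAUGGGACGGAG	24	84	1.36	36.0	-41.30	1
hvu-mir-1121	AGUAGUGAUCUAAACGCUCUUA	22	83	1.53	36.0	-45.90	1
hvu-mir-1122	UUUGUACAUCCGUAUGUAGU	20	120	1.28	33.0	-50.70	1
hvu-mir-1126	UCCACUAUGGACUACAUACGGAG	23	120	1.28	33.0	-50.70	1
hvu-mir-2004	UUUGUUUUUAUGUUAUUUUGUGAA	24	78	0.74	29.0	-16.90	1
hvu-mir-2007	CAAGAUAUUGGGUAUUUUUGUC	22	54	1.59	30.0	-25.90	1
hvu-mir-2014	AGCAAACAUAUCUGAGCACA	22	109	0.60	49.0	-32.20	1
hvu-mir-2019	CGGGUCGGCGCUGCAUGCGGC	21	71	0.53	65.0	-24.70	1
hvu-mir-2023a	UUUUGCCGGUUGAACGACCUCA	22	113	0.74	55.0	-46.00	1
hvu-mir-2024a	GCAGUUGCUGUCUCAAGCUU	20	118	1.02	44.0	-53.40	1
hvu-mir-2906	AACGGGCCGCUGCACAACUGG	21	254	0.77	63.0	-123.9	1
hvu-mir-2911	UAGUUGGUGGAGCGAUUUGUC	21	71	0.56	49.0	-19.6	1
hvu-mir-2914	CAUGGUGGUGACGGGUGACGGAG	23	63	0.61	56.0	-21.8	1
hvu-mir-5048	UAUUUGCAGGUUUUAGGUCUAA	22	354	0.88	31.0	-96.90	1
hvu-mir-5049	UCCUAAAUACUUGUUGUUGGG	21	81	1.37	43.0	-47.80	1
hvu-mir-5051	UUUGGCACCUUGAAACUGGGA	21	105	1.20	49.0	-61.90	1
hvu-mir-5052	ACCGGCUGGACGGUAGGCAUA	21	175	0.89	54.0	-85.00	1
hvu-mir-5066	AAGUGUAUAUGUGGAGUGUCU	21	80	0.33	44.0	-11.70	1
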