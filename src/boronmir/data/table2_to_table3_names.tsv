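# Map between count-table precursor ids and the labels the expression table
# prints. Most entries just drop the hvu- prefix; the hvu-mir157 -> miR156d
# correspondence is inferred from identical count quadruples and is flagged.
count_id	call_id	inferred
hvu-miR156	miR156	0
hvu-mir157	miR156d	1
hvu-miR165	miR165	0
hvu-miR169c	miR169c	0
hvu-miR171	miR171	0
hvu-miR171a	miR171a	0
hvu-miR172	miR172	0
hvu-miR397	miR397	0
hvu-miR399	miR399	0
hvu-miR408	miR408	0
hvu-miR444a	miR444a	0
hvu-miR444b	miR444b	0
hvu-miR444c	miR444c	0
hvu-miR1121	miR1121	0
hvu-miR2004	miR2004	0
hvu-miR2014	miR2014	0
hvu-miR2021	miR2021	0
hvu-miR2023a	miR2023a	0
hvu-miR2024a	miR2024a	0
hvu-miR5049	miR5049	0
hvu-miR5051	miR5051	0
hvu-miR5053	miR5053	0
hvu-miR5066	miR5066	0
hvu-miR5141	miR5141	0
hvu-miR5180a/miR5180b	miR5180a/miR5180b	0
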