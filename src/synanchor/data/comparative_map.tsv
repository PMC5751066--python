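rh_group	n_markers	ref_chromosome	n_transcripts
SQ1	30	OL5	1451
SQ2	19	OL1	1425
SQ3	12	OL6	1423
SQ4	19	OL4	1490
SQ5	14	OL23	777
SQ6	26	OL21	1197
SQ7	13	OL19	1046
SQ8	16	OL15	1204
SQ9	25	OL3	1307
SQ10	17	OL11	1269
SQ11	12	OL2	689
SQ12	36	OL8	1575
SQ13	5	OL17	1642
SQ14	12	OL13	1378
SQ15	32	OL9	1534
SQ16	18	OL16	1514
SQ17	17	OL12	1233
SQ18	16	OL10	1095
SQ19	24	OL14	1318
SQ20	16	OL22	1350
SQ21	17	OL20	993
SQ22	17	OL18	816
SQ23	23	OL24	1139
SQ24	31	OL7	1477
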