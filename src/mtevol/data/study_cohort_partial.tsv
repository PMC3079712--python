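# Partial transcription of a published 45-genome patient cohort:
# haplogroup-defining path variants plus only the per-sample variants
# documented in the study's printed summary tables (recurrent, tRNA,
# private and heteroplasmic variant tables).  The cohort's remaining
# private variation was never published per sample, so headline event
# totals computed from this file undercount the original analysis.
sample_id	carrier	variants
P01	0	813 930 1820 6446 6671 6680 10398 10400 14783
P02	0	73 295 3010 10398 11719 13708 14766 14798
P03	0	73 295 3010 10398 11719 13708 14766 14798
P04	1	73 295 7476 7789 10398 11377 11719 13708 14766 15257
P05	1	73 709 4917 5029 10463 11719 13368 14766 15928
P06	0	73 709 930 4917 5147 10463 11719 11812 13368 14766 15928
P07	0	73 263 2706 7028 10205 11719 14766
P08	0	73 263 2706 6776 7028 11719 14766
P09	1	73 263 709 2706 7028 10784R 11719 13101 14766
P10	0	73 263 2706 7028 9380 11719 14766
P11	1	73 263 2706 4992R 5144Y 5911 7028 11719 14766
P12	0	73 263 2706 7028 11719 14470 14766
P13	0	73 263 456 2706 4336 7028 11719 14766
P14	0	73 263 456 2706 4336 7028 11719 14766 15175
P15	0	73 263 2706 7028 11377 11719 14766 15924R
P16	0	73 263 2706 7028 11377 11719 14766 15924R
P17	0	72 73 263 11026 11719 14766 15904
P18	0	72 73 263 10081 11719 11914 14766 15904
P19	0	72 73 263 709 11719 14668 14766 15904
P20	1	73 263 2706 3010 3915 7028 11719 14766
P21	1	73 263 2706 3010 7028 9438 11719 14766
P22	1	73 263 2706 3010 7028 9962 11719 14766
P23	1	73 263 2706 3010 7028 9962 11719 14766
P24	0	73 263 2706 3010 5899 7028 11719 14766
P25	1	73 263 2706 3010 4674 7028 11719 14766
P26	1	73 263 2706 3010 4674 7028 11719 14766
P27	1	73 263 2706 3010 7028 8020 11719 14766
P28	1	73 263 2706 3010 7028 9066 11719 13759 14766
P29	0	73 263 2706 3010 7028 9066 11719 13759 14766 14831
P30	1	73 263 2706 3010 7028 11016 11719 14766
P31	0	73 263 2706 3010 7028 7861 11719 14766
P32	0	73 263 2706 3010 7028 11719 14766 16093Y
P33	1	73 827 961 11467 11719 12308 12372 14502 14766
P34	0	73 497 1811 9055 10398 11467 11719 12308 12372 14766 14798
P35	0	73 11467 11719 12308 12372 13105 14766
P36	0	73 4796 11467 11719 12103A 12308 12372 14766
P37	1	73 3197 5460 5656 7768 9477 11467 11719 12308 12372 14766 16286Y
P38	1	73 3197 5460 5656 7768 9477 10876 11467 11719 12308 12372 14766
P39	1	73 7561 11467 11719 12308 12372 14766
P40	0	73 11467 11719 11778 12308 12372 14766
P41	1	1719 4674 4960 8251 10238
P42	1	1719 4960 8251 9181 10238
P43	0	1719 6221 6371 8393 13708 15927
P44	0	146 150 152 2416 2789 7175 7521 8206 8544 10398 11914 16309
P45	1	146 152 2416 2789 7175 7521 8206 10398 12285G
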