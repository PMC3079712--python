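# Minimal Phylotree-style reference haplogroup tree covering the clades
# used by the bundled study cohort.  Tokens are rCRS-relative shorthand;
# '@' marks a back mutation (reversion) relative to an ancestral variant.
ROOT
	R	73 11719 14766
		R0	263
			H	2706 7028
				H1	3010
					H1j	13759
						H1j1	9066
				H5a	456 4336
				H8	709 13101
			HV0	72
				V	4580
				HV0a	15904
		U	11467 12308 12372
			U5	3197 9477
				U5b	7768
					U5b1	5656
						U5b1e	5460
			K	1811 9055 14798
				K1	497 10398
			U6	3348
				U6d	4336
		T	709 4917 10463 13368 15928
			T2	11812
				T2b	930 5147
		J	295 10398 13708
			J1	3010
				J1c	14798
			J2	7476 15257
				J2a	7789 11377
	N1	1719 10238
		N1b	4960 8251
	X	6221 6371
		X2	1719
			X2b	8393 13708 15927
	L2	146 150 152 2416 7521 8206 10398
		L2a	2789 7175
			L2a1	11914 16309
			L2a5	@150 12285G
	M	10398 10400 14783
		M1	6446 6680
			M1a	813
				M1a1b	930 6671
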