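# local known-variant catalogue (position, alt, source, disease_tag, confirmed);
# replaces live database queries — only worked-example rows are bundled
position	alt	source	disease_tag	confirmed
827	G	population:B4b'd'e	maternally inherited deafness (conflicting)	0
961	C	population:multiple	deafness / left ventricular non-compaction (unclear)	0
4336	C	population:H5a	ADPD / hearing loss & migraine (unclear)	0
4992	G	AP010974 (D4b2b1)		0
5911	T	population:R8a1	prostate cancer (reported)	0
10784	G	EF064320 (U6a1b)		0
11778	A		LHON (confirmed); progressive dystonia (confirmed)	1
12308	G	population:U	CPEO / stroke / CM / cancer risk (reported)	0
14502	C	population:M10	LHON (reported - possible synergistic)	0
14668	T	population:Z2	major depressive disorder (reported)	0
14831	A	population:L1c3b2	LHON (reported)	0
15924	G	common polymorphism		0
15927	A	population:X2b	multiple sclerosis (P.M)	0
15928	A	population:T	multiple sclerosis (P.M)	0
16093	C	common polymorphism		0
16286	T	common polymorphism		0
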