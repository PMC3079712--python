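# per-position tRNA conservation classes for bundled worked-example sites
position	conservation
4336	50%<x<90%
7476	50%<x<90%
7521	Different in human and mammalian consensus
7561	90%<x<100%
10463	50%<x<90%
12285	50%<x<90%
12308	100%
15904	Natural variable site
15927	Different in human and mammalian consensus
15928	50%<x<90%
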