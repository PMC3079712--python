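# positional hit counts on a worldwide phylogeny (>8700 complete genomes);
# only the rows used by the bundled worked examples are included — supply a
# full table for production use
position	hits
709	59
930	5
1719	31
3010	19
4674	2
4992	0
5144	0
10398	18
10784	1
11377	9
11914	37
13708	24
14798	7
15924	30
16093	79
16286	5
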