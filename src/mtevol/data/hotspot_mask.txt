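# Mutational hotspots excluded from phylogenetic reconstruction:
# the homopolymeric tract around 310, the 523-524 microsatellite,
# the 16182/16183 A>C transversions, insertions at 16193, 16519,
# and all length/point heteroplasmies.
302-316
523-524
16182C
16183C
16193+
16519
:heteroplasmy
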