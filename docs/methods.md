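# Methods

## Reference model and coordinates

The reference is a circular genome with 1-based inclusive coordinates in
rCRS-style numbering.  The coding region and the control region (D-loop,
wrapping the origin) partition the circle; by default the coding region is
577–16023 and region membership, not gene membership, decides whether an
event enters coding-region tallies (intergenic spacers inside the coding
region are annotated `non-coding` and labelled `-nc`).  Protein effects are
computed on the coding strand (reverse complement for minus-strand genes)
under the vertebrate mitochondrial code (translation table 2: AGA/AGG stop,
ATA Met, TGA Trp).  A protein span whose length is not a codon multiple is
treated as ending in an incomplete, polyadenylation-completed stop codon;
substitutions in the trailing partial codon are `undetermined` and excluded
from effect tallies.  Amino-acid classes are fixed as neutral apolar
{G,A,V,L,I,P,F,M,W}, neutral polar {S,T,C,Y,N,Q}, acidic polar {D,E},
basic polar {K,R,H}; VIAMT = {V,I,A,M,T}.  Codons containing the historic
placeholder N at 3107 translate to X and are excluded from enumeration.

### The bundled rCRS-like reference is synthetic

The true rCRS sequence is not redistributed with the package.  The bundled
fixture (`mtevol.rcrs_like`) keeps the real gene map — 13 protein genes, 22
tRNAs, 2 rRNAs at their standard coordinates, ATP8/ATP6 and ND4L/ND4
overlaps, ND6 and eight tRNAs on the minus strand — and generates the
sequence from a fixed seed, with bases locked at every documented
worked-example site so those sites annotate exactly as documented (e.g.
10398 ACC→GCC Thr→Ala; 8544 simultaneously TCA→TTA Ser→Leu in the ATP8
frame and ATC→ATT silent in the ATP6 frame), then repaired so no protein
frame contains an internal stop.  Consequently: tests of the annotation
engine against documented rows verify the engine's codon arithmetic,
strand handling, overlap handling and class mapping — they do not verify
the base content of the real rCRS.  Any real reference FASTA + annotation
TSV can be supplied instead.

One documented site cannot be honoured: with the ND2 frame fixed by the
three mutually consistent documented sites 4674 (Ile→Val, codon position
1), 4796 (silent, position 3) and 5029 (Met→Thr, position 2), position
4992 falls on codon position 1, where an A↔G change can never be silent in
this code; the published description of 4992 as synonymous is inconsistent
with those three rows and is not reproduced.

## Variant shorthand

`[@]POS[BASE|d|+SEQ]`, ranges `P1-P2d`.  A bare position is a transition
(alt = A↔G / C↔T partner of the reference base); an explicit base suffix is
a transversion — a suffix equal to the implied transition target is
rejected as contradictory; an IUPAC two-base code is a point heteroplasmy
whose alt is the non-reference base of the code; `@` marks a back mutation.
Formatting inverts parsing exactly (property-tested round trip).

## Hotspot mask

Masking is configuration, not code: a plain-text list of position ranges,
positions, insertion sites, exact tokens, and the `:heteroplasmy`
directive.  The bundled mask excludes the 302–316 homopolymer tract,
523–524 microsatellite, 16182C/16183C transversions, 16193 insertions,
16519, and all heteroplasmies.  The mask applies to phylogenetic placement
and tree building only; heteroplasmies are always triaged, and whether
masked sites enter spectrum tallies is the caller's choice of region
filter/profile view (by default spectrum counts come from tree events, so
masked sites are absent there too).

## Haplogroup calling

Every node of the reference tree is scored with
`|matched| − |missing| − w·|extras|` over its cumulative root-path variant
set (back mutations cancel ancestral variants; `w` defaults to 0).  Ties
break toward the deeper node, then the lexicographically smaller name.
This linear score is deliberately simpler than production
maximum-likelihood/Kulczynski classifiers; on cohorts whose lineages are
actually present in the reference tree it recovers the generating node
with accuracy 1.0 in the noise-free regime and ≥0.95 with several private
mutations per sample (measured by `scripts/acceptance.py`).  A profile's
`P + @P` pair annihilates before matching; a lone `@P` with no matching
path variant scores as an extra and is interpreted as "no difference from
the reference" during tree building.

## Backbone-constrained parsimony

Free maximum-parsimony topology search is NP-hard and unnecessary here:
the cohort tree is the reference-phylogeny subtree induced by the called
haplogroups.  Backbone edges carry the defining variants actually matched
by descendant samples; within each called node, samples sharing extra
variants are grouped greedily — the variant carried by most samples first,
ties by lowest position; the group's edge carries the full intersection of
its members' extras — recursively, and leftovers become terminal-edge
events.  Missing defining variants become `@POS` terminal events; `@`
events whose cancelled variant never entered upstream are pruned.
Non-nested sharing is resolved by duplicating the variant on both edges
and recording a recurrence, never by failing.  Root-to-tip replay of edge
events (with cancellation) reconstructs every masked profile exactly — a
property exercised over 1,000 random synthetic cohorts.

The parsimony score is the total event count.  On nested-sharing instances
with ≤6 tips the greedy construction equals the exhaustive Steiner optimum
(all binary topologies over the samples plus an all-absent reference leaf,
per-site Fitch); on arbitrary instances it is never below it.  "Young" vs
"old" events are operationalised as terminal vs internal edges; the
backbone flag separately records membership in the named reference
phylogeny.

## Spectrum statistics

Counting is event-based (one count per placed edge event, so recurrent
positions count once per edge), which is the convention needed for
whole-tree event totals; a distinct-variant mode is provided.  Ratios are
reported at 2 decimals and percentages at the nearest percent.  Pearson's
chi-square without continuity correction is the default (Yates is a flag);
a zero margin skips the test with a flag.  Gene-length correlations are
Pearson r/R² over (gene length in bp, event count), protein genes with
zero events included; fewer than 3 genes or zero variance is flagged
undefined.  The T/V amino-acid hit ratio is the mean per-amino-acid
involvement (aa_from or aa_to) in replacement events of {T,V} relative to
the mean over the remaining 18 amino acids.  Transversion spectra are
integer-normalised by the smallest positive target-base count.  Back
mutations count as events; their effect labels use the forward direction
of the underlying site (syn/nonsyn is direction-symmetric; stop gains on
reversion are not distinguished).  Carrier/non-carrier strata are assigned
per edge (the common stratum of all descendant tips, else `mixed`), so
stratum reports partition the total exactly.

## Evolutionary context

All external knowledge enters as local versioned TSVs: positional hit
counts on a worldwide phylogeny (missing position = 0), a known-variant
catalogue with exact (position, alt) lookup plus source/disease/confirmed
tags (replacing live MITOMAP/GenBank-style searches — "known in healthy"
is a catalogue source tag), and per-position tRNA conservation classes.
The bundled tables contain only the documented worked-example rows; full
tables are user-supplied.  Heteroplasmy triage stores the unordered base
pair (the direction convention of heteroplasmy reports is ambiguous),
deduplicates by (position, pair), and reports records even though
heteroplasmies are excluded from tree building.

## Synthetic cohorts

The generator emulates the study conditions of a mid-size clinical cohort:
45 samples by default, uniform haplogroup draw over a depth-3 parametric
tree (≈3 defining variants per branch, 3% reversion probability), Poisson
private mutations (λ = 3) drawn site-wise proportional to a rate model
(baseline 1, five hotspot sites ×50 — mimicking worldwide-phylogeny
hotspot behaviour), a 17.6:1 transition:transversion bias, 13% per-sample
heteroplasmy injection, and replacement filtering that keeps a
nonsynonymous draw with probability 0.5 (a simple selection proxy that
produces the expected second-codon-position deficit).  Mutations are drawn
on the actual simulated sequence, so synonymous/nonsynonymous ground truth
is exact; protein genes are generated with ATG starts, stop-free interiors
and terminal stops.  One seeded generator stream drives the whole path, so
identical configurations reproduce byte-identical bundles.

What the generator does *not* emulate: coalescent genealogies and realistic
branch-length/frequency joint structure, site-context mutability (CpG-like
effects), length heteroplasmy, sequencing artefacts, or phantom mutations.
Passing recovery tests therefore demonstrate correctness of the pipeline's
bookkeeping and detection logic under the stated generative model, not
robustness to real-world artefact structure.

## The bundled study cohort is a partial transcription

The bundled 45-sample cohort file reconstructs a published cohort from its
printed summary tables only: each sample carries its haplogroup-defining
path plus the per-sample variants documented in the recurrent/tRNA/
private/heteroplasmy tables (20 of 45 samples flagged as nuclear-mutation
carriers).  Structure documented per sample is fully recoverable — the
pipeline reproduces exactly ten recurrent coding-region positions
(709, 930, 1719, 3010, 4674, 10398, 11377, 11914, 13708, 14798) and six
heteroplasmies — but whole-cohort totals (e.g. the ~224 coding-region
substitution events of the full analysis, its 17.6:1 ts:tv or 1:2.02 ns:s
balance) require the complete per-sample variant lists, which were never
published; the corresponding acceptance test states the full expected
values and fails against the partial file by design.  Two further
transcription choices: the two carriers of the 4336 tRNA variant are
placed in a single clade (keeping the documented recurrent-position count
at exactly ten), and undocumented samples carry one unique filler private
variant each so that profiles are non-degenerate without creating
spurious recurrence.

## Problem sizes and numerical choices

Default test and acceptance runs use a 12 kb synthetic genome (3 kb for
the small property-test genome), cohorts of 6–400 samples, 1,000
reconstruction replicates and 10,000 random chi-square tables — sizes
chosen so the whole suite exercises every stage in well under a minute
while keeping statistical checks (binomial CIs, rank tests) adequately
powered.  Statistical comparisons use scipy (`chi2_contingency`,
`pearsonr`); independent oracles in the tests recompute the same
quantities from first-principles formulas.  Chi-square agreement is
asserted to 1e-9; floating-point ratio checks use the precision at which
each quantity is conventionally reported.
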