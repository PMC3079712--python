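# mtevol

Evolutionary analysis of complete human mitochondrial genomes, built for
clinical-cohort studies that ask whether the mtDNA variation seen in
patients is anything other than ordinary population variation.

When a cohort of patient mtDNA genomes is sequenced, candidate "pathogenic"
variants are often nominated simply because they are non-synonymous, absent
from databases ("novel"), or heteroplasmic.  The evolutionary counter-check
is to place every genome on the known worldwide mtDNA phylogeny and ask
whether the cohort's mutational spectrum — transition:transversion ratio,
codon-position usage, synonymous:non-synonymous balance, recurrence at known
hotspots, tRNA domain/conservation context — departs from what natural
population lineages show.  `mtevol` implements that workflow as a tested,
reusable pipeline:

- **Variant annotation** against an annotated circular reference (rCRS-style
  1-based numbering): region (coding 577–16023 vs D-loop), gene, codon
  position, synonymous/non-synonymous/stop under the vertebrate
  mitochondrial code (AGA/AGG stop, ATA Met), amino-acid physicochemical
  class changes, VIAMT membership, dual-gene overlaps (ATP8/ATP6-style),
  and tRNA secondary-structure domains.  Profiles use the compact
  forensic shorthand: bare position = transition, base suffix =
  transversion, `d` deletion, `+` insertion, IUPAC code = point
  heteroplasmy, `@` = back mutation.
- **Haplogroup calling** on a Phylotree-like reference tree with the linear
  score `|matched| − |missing| − w·|extras|`, plus case-control haplogroup
  frequency comparison (per-category 2×2 Pearson chi-square, Bonferroni
  threshold α/m).
- **Backbone-constrained maximum parsimony**: samples are placed on the
  reference phylogeny, shared extra variants are grouped greedily into
  sub-branches, expected-but-absent defining variants become back-mutation
  events, and replaying edge events from the root reconstructs every
  hotspot-masked profile exactly.  Positions on ≥2 independent edges are
  recurrent (homoplasic); terminal-edge events are private/young, internal
  ones haplogroup-defining/old.
- **Mutation-spectrum statistics** (event-based counting): ts:tv,
  transversion target-base spectrum, codon-position fractions, ns:s ratio,
  per-gene counts with gene-length correlations, young-vs-old ns:s
  chi-square, amino-acid hit ratios, carrier/non-carrier strata.
- **Evolutionary context**: positional recurrence scores from a local
  worldwide-phylogeny hit table, exact-match novelty checks against a local
  catalogue (no live database queries, ever), tRNA conservation classes and
  heteroplasmy triage.
- **Synthetic cohorts** with exported ground truth: simulated reference
  genomes with open reading frames, parametric haplogroup trees, per-site
  rate heterogeneity with hotspot multipliers, Poisson private mutations
  with a configurable ts:tv bias and replacement filtering, and injected
  heteroplasmies — so every stage is testable end-to-end offline.

The bundled reference is a **synthetic rCRS-like genome**: real rCRS gene
coordinates and numbering (16,569 bp, placeholder N at 3107) with a
constructed sequence whose bases are fixed at the documented worked-example
sites.  It is a fixture, not the true rCRS sequence; point the pipeline at
any real reference FASTA + annotation table for production use.

## Worked example

```
$ mtevol annotate 10398 8544 12308
{"token": "10398", "gene": "ND3", "region": "protein", "effect": "nonsynonymous",
 "codon_position": 1, "aa_change": "T-A", "aa_class_change": "neutral polar-neutral apolar"}
{"token": "8544", "gene": "ATP8", "region": "protein", "effect": "nonsynonymous",
 "codon_position": 2, "aa_change": "S-L", "aa_class_change": "neutral polar-neutral apolar"}
{"token": "8544", "gene": "ATP6", "region": "protein", "effect": "synonymous", "codon_position": 3}
{"token": "12308", "gene": "tRNA-Leu(CUN)", "region": "tRNA", "domain": "Variable loop"}
```

10398 A>G replaces Thr with Ala at the first codon position of *ND3* (a
change within the well-tolerated V/I/A/M/T group); 8544 C>T sits in the
ATP8/ATP6 overlap and is a Ser→Leu replacement in one reading frame but
silent in the other; 12308 A>G falls in the variable loop of
tRNA-Leu(CUN).

Running the pipeline on the bundled 45-sample cohort transcription:

```python
from mtevol.datasets import (bundled_cohort, bundled_phylotree, bundled_mask,
                             bundled_reference, bundled_rates, bundled_catalogue)
from mtevol import call_haplogroup, build_mp_tree, partition_variants
from mtevol.evocontext import triage_heteroplasmies

ref, tree, mask = bundled_reference(), bundled_phylotree(), bundled_mask()
cohort = bundled_cohort()
tokens = {p.sample_id: p.tokens(mask) for p in cohort}
calls = {s: call_haplogroup(s, t, tree) for s, t in tokens.items()}
mp = build_mp_tree(tokens, tree, calls)
print(sorted(partition_variants(mp).recurrent_positions(577, 16023)))
# [709, 930, 1719, 3010, 4674, 10398, 11377, 11914, 13708, 14798]
print(len(triage_heteroplasmies({p.sample_id: p.variants for p in cohort},
                                bundled_rates(), bundled_catalogue(), ref)))
# 6
```

Ten coding-region positions recur on independent branches of the cohort
tree (homoplasies — mostly known phylogenetic hotspots), and six distinct
heteroplasmies are triaged with their worldwide recurrence scores and
known-in-healthy flags.  The cohort file carries only the per-sample
variants documented in published summary tables, so whole-cohort event
totals computed from it undercount the original full-genome analysis (see
`docs/methods.md`).

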