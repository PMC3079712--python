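# File formats

All files are plain text, tab-separated where columnar, with `#` comment
lines permitted before and between rows.  Positions are 1-based inclusive
on the reference.

## Reference

- **FASTA** — exactly one record; A/C/G/T/N.
- **Annotation TSV** — columns
  `gene  type  start  end  strand  frame  domain_map_id`;
  `type ∈ {protein, tRNA, rRNA, non-coding}`; `strand ∈ {+, -}`; `frame` is
  the 0–2 offset of the first codon base (from `start` on `+`, from `end`
  on `-`); `domain_map_id` keys tRNAs into the domain table.  An optional
  header comment `# coding_range=LO-HI` overrides the default (annotation
  extent).
- **tRNA domain TSV** — columns `map_id  position  domain`.

## Profiles

`sample_id  carrier  variants` — one sample per row; `carrier` is `1`/`0`
or empty/`?` for unknown; `variants` is a whitespace-separated list of
shorthand tokens:

| token      | meaning                                   |
|------------|-------------------------------------------|
| `3010`     | transition (alt implied by reference base) |
| `16182C`   | transversion to C                          |
| `523-524d` | deletion of 523–524 (`523d` single site)   |
| `310+CC` / `310+2C` | insertion after 310               |
| `16093Y`   | point heteroplasmy (IUPAC pair)            |
| `@150`     | back mutation (reversion)                  |

## Haplogroup tree

Indented UTF-8 text, one node per line, one leading TAB per level:
`name<TAB>token token ...`.  A `@POS` token must cancel a variant carried
on the node's root path.

## Hotspot mask

One rule per line: `LO-HI` (position range), `POS` (all variants at POS),
`POS+` (insertions at POS), an exact token (`16182C`, `523-524d`), or the
directive `:heteroplasmy`.

## Knowledge tables

- **Rate table** — `position  hits` (non-negative ints; missing = 0).
- **Known-variant catalogue** — `position  alt  source  disease_tag
  confirmed` (`confirmed` 0/1).
- **tRNA conservation** — `position  conservation`.
- **Control counts** — `category  count` (haplogroup frequency categories).

## Pipeline outputs (`mtevol run -o DIR`)

- `calls.tsv` — `sample  haplogroup  score  missing  extras`.
- `tree.nwk` — newick; leaf labels are sample ids, branch length = number
  of mutation events on the edge.
- `events.tsv` — `edge  token  label  status  haplogroup  recurrent`;
  `label` uses the branch-annotation conventions (`s` synonymous, `-t`
  tRNA, `-r` rRNA, `-stp` stop, `-nc` non-coding in the coding region,
  `(X-Y)` replacement, `*` prefix for dual-gene positions); `status` is
  `private` or `haplogroup-defining`; `recurrent` is 0/1.
- `spectrum.json` — provenance header (`# key=value` lines) then a JSON
  object with `total` and per-stratum summaries.
- `spectrum.tsv` — flat `category  level  count` table.
- `frequency.tsv` — per-category 2×2 chi-square results plus the
  Bonferroni threshold (only when control counts are supplied).
- `triage.tsv` — `position  base_pair  locus  carriers  rate_score
  known_in_healthy  sources`.
- `novelty.tsv` — `token  position  gene  effect  status  rate_score
  disease_tags  confirmed` for private variants.
- `provenance.txt` — package version, seed, input digests and flags; the
  same block heads every derived output, so reruns are byte-identical.
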