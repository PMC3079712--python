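"""Functional annotation of variants against the reference model.

Every annotation overlapping the variant position yields one consequence
record (the ATP8/ATP6-style dual-gene case gives two).  Codon effects are
computed on the coding strand under the vertebrate mitochondrial code, and
amino-acid replacements are classified into the four physicochemical classes
(neutral apolar / neutral polar / acidic polar / basic polar) plus VIAMT
membership.
"""

from __future__ import annotations

from dataclasses import dataclass

from .reference import COMPLEMENT, VIAMT, GeneAnnotation, ReferenceModel, aa_class, translate_codon
from .variants import Variant


@dataclass(frozen=True)
class Consequence:
    """Per-gene consequence of one variant."""

    gene: str
    region_class: str  # protein | tRNA | rRNA | non-coding | control
    effect: str | None = None  # synonymous | nonsynonymous | stop | frameshift | undetermined
    codon_position: int | None = None  # 1/2/3, proteins only
    codon_number: int | None = None
    aa_from: str | None = None
    aa_to: str | None = None
    domain: str | None = None  # tRNA secondary-structure domain
    overlap: bool = False  # position shared by >=2 genes
    primary: bool = True  # the consequence used for cohort-level counts

    @property
    def aa_class_from(self) -> str | None:
        return aa_class(self.aa_from) if self.aa_from and self.aa_from != "X" else None

    @property
    def aa_class_to(self) -> str | None:
        return aa_class(self.aa_to) if self.aa_to and self.aa_to != "X" else None

    @property
    def aa_class_change(self) -> str | None:
        if self.aa_class_from is None or self.aa_class_to is None:
            return None
        return f"{self.aa_class_from}-{self.aa_class_to}"

    @property
    def viamt(self) -> bool:
        """True when the replacement stays within the tolerated VIAMT group."""
        return (
            self.effect == "nonsynonymous"
            and self.aa_from in VIAMT
            and self.aa_to in VIAMT
        )


@dataclass(frozen=True)
class VariantAnnotation:
    variant: Variant
    consequences: tuple[Consequence, ...]

    @property
    def primary(self) -> Consequence:
        return self.consequences[0]

    @property
    def region_class(self) -> str:
        return self.primary.region_class

    @property
    def effect(self) -> str | None:
        return self.primary.effect


def _protein_consequence(
    v: Variant, ann: GeneAnnotation, ref: ReferenceModel, overlap: bool
) -> Consequence:
    if v.is_indel:
        # indels in protein genes are frame-affecting; no amino-acid call
        return Consequence(ann.gene, "protein", effect="frameshift", overlap=overlap)
    codon_no, codon_pos = ref.codon_index(ann, v.position)
    if codon_no > ref.n_codons(ann):
        # inside the trailing partial (polyadenylation-completed) codon
        return Consequence(
            ann.gene, "protein", effect="undetermined",
            codon_position=codon_pos, codon_number=codon_no, overlap=overlap,
        )
    codon = ref.codon(ann, codon_no)
    ref_allele, alt_allele = v.ref, v.alt
    if ann.strand == "-":
        ref_allele, alt_allele = COMPLEMENT[ref_allele], COMPLEMENT[alt_allele]
    assert codon[codon_pos - 1] == ref_allele, (
        f"reference mismatch at {v.position} in {ann.gene}"
    )
    mutated = codon[: codon_pos - 1] + alt_allele + codon[codon_pos:]
    aa_from, aa_to = translate_codon(codon), translate_codon(mutated)
    if "X" in (aa_from, aa_to):
        effect = "undetermined"
    elif aa_from == aa_to:
        effect = "synonymous"
    elif "*" in (aa_from, aa_to):
        effect = "stop"
    else:
        effect = "nonsynonymous"
    return Consequence(
        ann.gene, "protein", effect=effect,
        codon_position=codon_pos, codon_number=codon_no,
        aa_from=aa_from, aa_to=aa_to, overlap=overlap,
    )


def annotate_variant(v: Variant, ref: ReferenceModel) -> VariantAnnotation:
    """Annotate one variant with all per-gene consequences.

    Exactly one consequence per overlapping annotation; a position outside
    every feature yields a single 'control' (D-loop) or 'non-coding'
    (intergenic spacer within the coding region) record.  The first
    consequence (reference-table order) is the primary one used for
    cohort-level counting.
    """
    if v.ref != "-" and not v.back_mutation and ref.base(v.position) != v.ref:
        raise ValueError(
            f"variant {v} ref allele {v.ref} does not match reference base "
            f"{ref.base(v.position)}"
        )
    features = ref.features_at(v.position)
    records: list[Consequence] = []
    overlap = len(features) > 1
    for i, ann in enumerate(features):
        if ann.feature_type == "protein":
            c = _protein_consequence(v, ann, ref, overlap)
        elif ann.feature_type == "tRNA":
            domain = ref.domain_maps.get(ann.domain_map_id, {}).get(v.position, "")
            c = Consequence(ann.gene, "tRNA", domain=domain, overlap=overlap)
        elif ann.feature_type == "rRNA":
            c = Consequence(ann.gene, "rRNA", overlap=overlap)
        else:
            c = Consequence(ann.gene, "non-coding", overlap=overlap)
        if i > 0:
            c = Consequence(**{**c.__dict__, "primary": False})
        records.append(c)
    if not records:
        region = "non-coding" if ref.in_coding_region(v.position) else "control"
        records.append(Consequence("", region))
    return VariantAnnotation(variant=v, consequences=tuple(records))


def figure_label(va: VariantAnnotation) -> str:
    """Branch-annotation suffix in the conventional tree-figure style.

    's' synonymous, '-t' tRNA, '-r' rRNA, '-stp' stop, '-nc' non-coding in the
    coding region, '(X-Y)' amino-acid replacement; control-region variants are
    unsuffixed.  An asterisk marks positions shared by two genes.
    """
    c = va.primary
    star = "*" if c.overlap else ""
    if c.region_class == "protein":
        if c.effect == "synonymous":
            return star + "s"
        if c.effect == "stop":
            return star + "-stp"
        if c.effect == "nonsynonymous":
            return f"{star}({c.aa_from}-{c.aa_to})"
        return star
    return star + {"tRNA": "-t", "rRNA": "-r", "non-coding": "-nc", "control": ""}[
        c.region_class
    ]
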