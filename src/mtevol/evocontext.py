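"""Evolutionary-context scoring of observed variants.

All external knowledge enters as local, versioned TSV tables: a positional
recurrence-rate table (hit counts on a worldwide phylogeny), a known-variant
catalogue with source/disease tags for novelty checks (replacing live
database queries), and a per-position tRNA conservation-class table.
Verdicts are pure functions of the supplied tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .annotate import annotate_variant
from .reference import ReferenceModel
from .variants import Variant


@dataclass
class RateTable:
    """position -> hit count on a worldwide phylogeny (missing = 0)."""

    hits: dict[int, int]
    provenance: str = ""

    def score(self, position: int) -> int:
        return self.hits.get(position, 0)

    @classmethod
    def from_file(cls, path: str | Path) -> "RateTable":
        hits: dict[int, int] = {}
        provenance = ""
        for raw in Path(path).read_text().splitlines():
            if raw.startswith("#"):
                provenance = provenance or raw.lstrip("# ").strip()
                continue
            if not raw.strip() or raw.startswith("position\t"):
                continue
            pos, n = raw.split("\t")[:2]
            count = int(n)
            if count < 0:
                raise ValueError(f"negative hit count at position {pos}")
            hits[int(pos)] = count
        return cls(hits=hits, provenance=provenance)


def recurrence_score(position: int, table: RateTable) -> int:
    return table.score(position)


@dataclass(frozen=True)
class CatalogueRecord:
    position: int
    alt: str
    source: str  # e.g. population-survey accession or database name
    disease_tag: str = ""
    confirmed: bool = False  # confirmed-pathogenic flag


@dataclass
class KnownVariantCatalogue:
    """Exact-match (position, alt) lookup of previously reported variants."""

    records: dict[tuple[int, str], list[CatalogueRecord]] = field(default_factory=dict)

    def add(self, rec: CatalogueRecord) -> None:
        self.records.setdefault((rec.position, rec.alt), []).append(rec)

    def lookup(self, position: int, alt: str) -> list[CatalogueRecord]:
        return self.records.get((position, alt), [])

    @classmethod
    def from_file(cls, path: str | Path) -> "KnownVariantCatalogue":
        cat = cls()
        for raw in Path(path).read_text().splitlines():
            if not raw.strip() or raw.startswith("#") or raw.startswith("position\t"):
                continue
            f = raw.split("\t")
            cat.add(
                CatalogueRecord(
                    position=int(f[0]),
                    alt=f[1],
                    source=f[2] if len(f) > 2 else "",
                    disease_tag=f[3] if len(f) > 3 else "",
                    confirmed=bool(int(f[4])) if len(f) > 4 and f[4] else False,
                )
            )
        return cat


@dataclass
class NoveltyVerdict:
    status: str  # 'known' | 'novel'
    sources: list[str]
    disease_tags: list[str]
    confirmed_pathogenic: bool


def novelty_check(v: Variant, catalogue: KnownVariantCatalogue) -> NoveltyVerdict:
    """Exact (position, alt) novelty verdict against the local catalogue."""
    recs = catalogue.lookup(v.position, v.alt)
    if not recs:
        return NoveltyVerdict("novel", [], [], False)
    return NoveltyVerdict(
        status="known",
        sources=[r.source for r in recs if r.source],
        disease_tags=[r.disease_tag for r in recs if r.disease_tag],
        confirmed_pathogenic=any(r.confirmed for r in recs),
    )


# --- tRNA context ---------------------------------------------------------


@dataclass
class ConservationTable:
    """position -> printed conservation class for tRNA sites."""

    classes: dict[int, str]

    @classmethod
    def from_file(cls, path: str | Path) -> "ConservationTable":
        classes: dict[int, str] = {}
        for raw in Path(path).read_text().splitlines():
            if not raw.strip() or raw.startswith("#") or raw.startswith("position\t"):
                continue
            pos, klass = raw.split("\t")[:2]
            classes[int(pos)] = klass
        return cls(classes=classes)

    def lookup(self, position: int) -> str:
        return self.classes.get(position, "")


@dataclass
class TrnaContext:
    gene: str
    domain: str
    conservation: str


def trna_context(
    v: Variant, ref: ReferenceModel, conservation: ConservationTable | None = None
) -> TrnaContext:
    """Secondary-structure domain and conservation class of a tRNA variant."""
    for ann in ref.features_at(v.position):
        if ann.feature_type == "tRNA":
            domain = ref.domain_maps.get(ann.domain_map_id, {}).get(v.position, "")
            klass = conservation.lookup(v.position) if conservation else ""
            return TrnaContext(gene=ann.gene, domain=domain, conservation=klass)
    raise ValueError(f"position {v.position} is not inside a tRNA gene")


# --- heteroplasmy triage --------------------------------------------------


@dataclass
class HeteroplasmyRecord:
    position: int
    base_pair: frozenset[str]  # unordered observed allele pair
    locus: str
    carriers: list[str]
    rate_score: int
    known_in_healthy: bool
    sources: list[str]
    ambiguous: bool = False

    @property
    def base_pair_label(self) -> str:
        ref_first = sorted(self.base_pair)
        return "/".join(ref_first)


def triage_heteroplasmies(
    profiles: dict[str, list[Variant]],
    table: RateTable,
    catalogue: KnownVariantCatalogue,
    ref: ReferenceModel,
) -> list[HeteroplasmyRecord]:
    """One deduplicated record per heteroplasmic (position, base pair).

    Heteroplasmies are excluded from tree building by the hotspot mask but
    are always reported here, with gene/locus, the worldwide recurrence
    score and a known-in-healthy flag from the catalogue (matching either
    allele of the pair at the position).
    """
    found: dict[tuple[int, frozenset[str]], HeteroplasmyRecord] = {}
    for sample, variants in profiles.items():
        for v in variants:
            if not v.heteroplasmic:
                continue
            pair = frozenset((v.ref, v.alt))
            key = (v.position, pair)
            if key not in found:
                anns = ref.features_at(v.position)
                if anns:
                    locus = "/".join(a.gene for a in anns)
                else:
                    locus = "D-loop" if not ref.in_coding_region(v.position) else "non-coding"
                recs = [
                    r
                    for allele in sorted(pair)
                    for r in catalogue.lookup(v.position, allele)
                ]
                found[key] = HeteroplasmyRecord(
                    position=v.position,
                    base_pair=pair,
                    locus=locus,
                    carriers=[],
                    rate_score=table.score(v.position),
                    known_in_healthy=any(not r.disease_tag for r in recs),
                    sources=[r.source for r in recs if r.source],
                    ambiguous=len(pair) != 2,
                )
            found[key].carriers.append(sample)
    records = sorted(found.values(), key=lambda r: (r.position, r.base_pair_label))
    for r in records:
        r.carriers.sort()
    return records


def write_triage(records: list[HeteroplasmyRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "position\tbase_pair\tlocus\tcarriers\trate_score\t"
            "known_in_healthy\tsources\n"
        )
        for r in records:
            fh.write(
                f"{r.position}\t{r.base_pair_label}\t{r.locus}\t"
                f"{','.join(r.carriers)}\t{r.rate_score}\t"
                f"{int(r.known_in_healthy)}\t{';'.join(r.sources)}\n"
            )


def write_novelty_table(
    variants: list[Variant],
    catalogue: KnownVariantCatalogue,
    table: RateTable,
    ref: ReferenceModel,
    path: str | Path,
) -> None:
    """Novelty/context report for a list of (typically private) variants."""
    with open(path, "w") as fh:
        fh.write(
            "token\tposition\tgene\teffect\tstatus\trate_score\t"
            "disease_tags\tconfirmed\n"
        )
        for v in sorted(variants, key=lambda v: v.position):
            verdict = novelty_check(v, catalogue)
            ann = annotate_variant(v, ref)
            c = ann.primary
            fh.write(
                f"{v}\t{v.position}\t{c.gene}\t{c.effect or c.region_class}\t"
                f"{verdict.status}\t{table.score(v.position)}\t"
                f"{';'.join(verdict.disease_tags)}\t"
                f"{int(verdict.confirmed_pathogenic)}\n"
            )
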