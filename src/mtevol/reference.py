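"""Circular mitochondrial reference model.

Holds the reference sequence (1-based, rCRS-style numbering), strand-aware
gene/region annotations and the vertebrate mitochondrial genetic code, and
provides the codon arithmetic used by the variant annotation engine.

The genome is circular: the control region (D-loop) wraps the origin, while
the coding region is the complementary arc (rCRS: 577-16023).  All
coordinates are 1-based and inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

# Vertebrate mitochondrial code (NCBI translation table 2):
# AGA/AGG are stops, ATA is Met, TGA is Trp.
MITO_TABLE = 2

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

# Physicochemical classes used for replacement-substitution bookkeeping.
NEUTRAL_APOLAR = frozenset("GAVLIPFMW")
NEUTRAL_POLAR = frozenset("STCYNQ")
ACIDIC_POLAR = frozenset("DE")
BASIC_POLAR = frozenset("KRH")
# Replacements within {V,I,A,M,T} are preferentially tolerated in mtDNA
# protein evolution.
VIAMT = frozenset("VIAMT")

_CLASS_NAMES = (
    (NEUTRAL_APOLAR, "neutral apolar"),
    (NEUTRAL_POLAR, "neutral polar"),
    (ACIDIC_POLAR, "acidic polar"),
    (BASIC_POLAR, "basic polar"),
)


def aa_class(aa: str) -> str:
    """Physicochemical class of a one-letter amino acid (stop -> 'stop')."""
    if aa == "*":
        return "stop"
    for members, name in _CLASS_NAMES:
        if aa in members:
            return name
    raise ValueError(f"unknown amino acid {aa!r}")


def translate_codon(codon: str) -> str:
    """One-letter translation of a codon under the mitochondrial code.

    Returns '*' for stops and 'X' when the codon contains an N.
    """
    if "N" in codon:
        return "X"
    return str(Seq(codon).translate(table=MITO_TABLE))


class FormatError(ValueError):
    """Malformed input file or token."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated feature on the circular reference.

    ``frame`` is the offset (0-2) of the first codon base relative to
    ``start`` (plus strand) or ``end`` (minus strand); only meaningful for
    protein genes.  ``domain_map_id`` keys tRNA genes into a per-position
    secondary-structure domain table.
    """

    gene: str
    feature_type: str  # protein | tRNA | rRNA | non-coding
    start: int
    end: int
    strand: str
    frame: int = 0
    domain_map_id: str = ""

    def __post_init__(self) -> None:
        if self.feature_type not in {"protein", "tRNA", "rRNA", "non-coding"}:
            raise FormatError(f"bad feature type {self.feature_type!r}")
        if self.strand not in {"+", "-"}:
            raise FormatError(f"strand must be + or -, got {self.strand!r}")
        if self.start < 1 or self.end < self.start:
            raise FormatError(
                f"bad coordinates {self.start}-{self.end} for {self.gene}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def incomplete_stop(self) -> bool:
        """True when the span does not hold whole codons (protein genes whose
        stop codon is completed by post-transcriptional polyadenylation)."""
        return self.feature_type == "protein" and (self.length - self.frame) % 3 != 0

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class ReferenceModel:
    """Circular reference genome + annotations + region partition."""

    name: str
    sequence: str
    annotations: list[GeneAnnotation]
    coding_range: tuple[int, int]
    domain_maps: dict[str, dict[int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not set(self.sequence) <= set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise FormatError(f"non-ACGTN characters in sequence: {bad}")
        n = len(self.sequence)
        for ann in self.annotations:
            if ann.end > n:
                raise FormatError(
                    f"annotation {ann.gene} ends at {ann.end} beyond "
                    f"sequence length {n}"
                )
        lo, hi = self.coding_range
        if not (1 <= lo <= hi <= n):
            raise FormatError(f"bad coding range {self.coding_range}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def control_range(self) -> tuple[int, int]:
        """Complement of the coding range, wrapping the origin."""
        lo, hi = self.coding_range
        return (hi + 1 if hi < self.length else 1, lo - 1 if lo > 1 else self.length)

    def base(self, position: int) -> str:
        if not 1 <= position <= self.length:
            raise ValueError(f"position {position} outside 1..{self.length}")
        return self.sequence[position - 1]

    def in_coding_region(self, position: int) -> bool:
        lo, hi = self.coding_range
        return lo <= position <= hi

    def features_at(self, position: int) -> list[GeneAnnotation]:
        """All annotations overlapping a position, in reference-table order."""
        return [a for a in self.annotations if a.contains(position)]

    def protein_genes(self) -> list[GeneAnnotation]:
        return [a for a in self.annotations if a.feature_type == "protein"]

    # --- codon arithmetic -------------------------------------------------

    def codon_index(self, ann: GeneAnnotation, position: int) -> tuple[int, int]:
        """(codon number 1-based, within-codon position 1/2/3) on the coding
        strand of a protein gene."""
        if ann.feature_type != "protein" or not ann.contains(position):
            raise ValueError(f"{position} is not inside protein gene {ann.gene}")
        if ann.strand == "+":
            off = position - ann.start - ann.frame
        else:
            off = ann.end - ann.frame - position
        if off < 0:
            raise ValueError(f"{position} precedes the reading frame of {ann.gene}")
        return off // 3 + 1, off % 3 + 1

    def codon_positions(self, ann: GeneAnnotation, codon_number: int) -> list[int]:
        """Reference positions of a codon, ordered along the coding strand."""
        if ann.strand == "+":
            first = ann.start + ann.frame + 3 * (codon_number - 1)
            return [first, first + 1, first + 2]
        first = ann.end - ann.frame - 3 * (codon_number - 1)
        return [first, first - 1, first - 2]

    def codon(self, ann: GeneAnnotation, codon_number: int) -> str:
        """Codon sequence on the coding strand (complemented for '-')."""
        bases = [self.base(p) for p in self.codon_positions(ann, codon_number)]
        if ann.strand == "-":
            bases = [COMPLEMENT[b] for b in bases]
        return "".join(bases)

    def n_codons(self, ann: GeneAnnotation) -> int:
        """Number of complete codons in a protein gene."""
        return (ann.length - ann.frame) // 3


# --- file I/O -------------------------------------------------------------

_ANN_COLUMNS = ["gene", "type", "start", "end", "strand", "frame", "domain_map_id"]


def load_reference(
    fasta_path: str | Path,
    annotation_tsv_path: str | Path,
    domain_tsv_path: str | Path | None = None,
) -> ReferenceModel:
    """Load a reference genome from a single-record FASTA plus a feature TSV.

    The TSV has columns gene/type/start/end/strand/frame/domain_map_id and may
    carry ``# coding_range=LO-HI`` in a comment header; without it the coding
    range is the annotation extent.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise FormatError(f"expected exactly one FASTA record, got {len(records)}")
    seq = str(records[0].seq).upper()

    coding_range = None
    annotations: list[GeneAnnotation] = []
    for line_no, raw in enumerate(Path(annotation_tsv_path).read_text().splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            m = re.search(r"coding_range=(\d+)-(\d+)", line)
            if m:
                coding_range = (int(m.group(1)), int(m.group(2)))
            continue
        fields = line.split("\t")
        if fields[: len(_ANN_COLUMNS)] == _ANN_COLUMNS:
            continue  # header row
        if len(fields) < 6:
            raise FormatError(f"line {line_no}: expected >=6 columns, got {len(fields)}")
        try:
            start, end = int(fields[2]), int(fields[3])
            frame = int(fields[5]) if fields[5] else 0
        except ValueError as exc:
            raise FormatError(f"line {line_no}: malformed coordinates") from exc
        annotations.append(
            GeneAnnotation(
                gene=fields[0],
                feature_type=fields[1],
                start=start,
                end=end,
                strand=fields[4],
                frame=frame,
                domain_map_id=fields[6] if len(fields) > 6 else "",
            )
        )
    if not annotations:
        raise FormatError("annotation table is empty")
    if coding_range is None:
        coding_range = (
            min(a.start for a in annotations),
            max(a.end for a in annotations),
        )
    domain_maps: dict[str, dict[int, str]] = {}
    if domain_tsv_path is not None:
        domain_maps = load_domain_maps(domain_tsv_path)
    return ReferenceModel(
        name=records[0].id,
        sequence=seq,
        annotations=annotations,
        coding_range=coding_range,
        domain_maps=domain_maps,
    )


def load_domain_maps(path: str | Path) -> dict[str, dict[int, str]]:
    """tRNA secondary-structure domain table: map_id -> {position: domain}."""
    maps: dict[str, dict[int, str]] = {}
    for raw in Path(path).read_text().splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if fields[0] == "map_id":
            continue
        map_id, pos, domain = fields[0], int(fields[1]), fields[2]
        maps.setdefault(map_id, {})[pos] = domain
    return maps


def write_reference(ref: ReferenceModel, fasta_path: str | Path, tsv_path: str | Path) -> None:
    """Write a ReferenceModel back to FASTA + annotation TSV (round-trips)."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{ref.name}\n")
        for i in range(0, ref.length, 70):
            fh.write(ref.sequence[i : i + 70] + "\n")
    with open(tsv_path, "w") as fh:
        lo, hi = ref.coding_range
        fh.write(f"# coding_range={lo}-{hi}\n")
        fh.write("\t".join(_ANN_COLUMNS) + "\n")
        for a in ref.annotations:
            fh.write(
                f"{a.gene}\t{a.feature_type}\t{a.start}\t{a.end}\t{a.strand}"
                f"\t{a.frame}\t{a.domain_map_id}\n"
            )


def write_domain_maps(maps: dict[str, dict[int, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("map_id\tposition\tdomain\n")
        for map_id in sorted(maps):
            for pos in sorted(maps[map_id]):
                fh.write(f"{map_id}\t{pos}\t{maps[map_id][pos]}\n")
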