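"""Bundled SYNTHETIC rCRS-like human mitochondrial reference.

The gene map reproduces the standard human mtDNA annotation on rCRS
numbering (16,569 bp, coding region 577-16023, placeholder N at 3107,
ATP8/ATP6 and ND4L/ND4 overlaps, ND6 and several tRNAs on the minus
strand).  The *sequence itself is synthetic*: it is generated from a fixed
seed, with bases locked at the worked-example positions of the analysis
(e.g. 10398 ACC->GCC Thr->Ala in ND3, the dual-frame 8544 site, the tRNA
table rows) so that the annotation engine reproduces the documented
consequences at those sites, and repaired so that no protein gene contains
an internal stop codon.  It is a stand-in fixture for the true rCRS, which
is not redistributed here; the engine accepts any user-supplied reference.
"""

from __future__ import annotations

import numpy as np

from .reference import COMPLEMENT, GeneAnnotation, ReferenceModel, translate_codon

LENGTH = 16569
CODING_RANGE = (577, 16023)
_SEED = 20110419

# gene, type, start, end, strand (standard rCRS coordinates)
GENE_TABLE: list[tuple[str, str, int, int, str]] = [
    ("tRNA-Phe", "tRNA", 577, 647, "+"),
    ("12S rRNA", "rRNA", 648, 1601, "+"),
    ("tRNA-Val", "tRNA", 1602, 1670, "+"),
    ("16S rRNA", "rRNA", 1671, 3229, "+"),
    ("tRNA-Leu(UUR)", "tRNA", 3230, 3304, "+"),
    ("ND1", "protein", 3307, 4262, "+"),
    ("tRNA-Ile", "tRNA", 4263, 4331, "+"),
    ("tRNA-Gln", "tRNA", 4329, 4400, "-"),
    ("tRNA-Met", "tRNA", 4402, 4469, "+"),
    ("ND2", "protein", 4470, 5511, "+"),
    ("tRNA-Trp", "tRNA", 5512, 5579, "+"),
    ("tRNA-Ala", "tRNA", 5587, 5655, "-"),
    ("tRNA-Asn", "tRNA", 5657, 5729, "-"),
    ("tRNA-Cys", "tRNA", 5761, 5826, "-"),
    ("tRNA-Tyr", "tRNA", 5826, 5891, "-"),
    ("COX1", "protein", 5904, 7445, "+"),
    ("tRNA-Ser(UCN)", "tRNA", 7446, 7514, "-"),
    ("tRNA-Asp", "tRNA", 7518, 7585, "+"),
    ("COX2", "protein", 7586, 8269, "+"),
    ("tRNA-Lys", "tRNA", 8295, 8364, "+"),
    ("ATP8", "protein", 8366, 8572, "+"),
    ("ATP6", "protein", 8527, 9207, "+"),
    ("COX3", "protein", 9207, 9990, "+"),
    ("tRNA-Gly", "tRNA", 9991, 10058, "+"),
    ("ND3", "protein", 10059, 10404, "+"),
    ("tRNA-Arg", "tRNA", 10405, 10469, "+"),
    ("ND4L", "protein", 10470, 10766, "+"),
    ("ND4", "protein", 10760, 12137, "+"),
    ("tRNA-His", "tRNA", 12138, 12206, "+"),
    ("tRNA-Ser(AGY)", "tRNA", 12207, 12265, "+"),
    ("tRNA-Leu(CUN)", "tRNA", 12266, 12336, "+"),
    ("ND5", "protein", 12337, 14148, "+"),
    ("ND6", "protein", 14149, 14673, "-"),
    ("tRNA-Glu", "tRNA", 14674, 14742, "-"),
    ("CYTB", "protein", 14747, 15887, "+"),
    ("tRNA-Thr", "tRNA", 15888, 15953, "+"),
    ("tRNA-Pro", "tRNA", 15956, 16023, "-"),
]

# Whole codons locked on plus-strand protein genes (key = position of the
# first codon base on the reference strand), chosen so the worked-example
# substitutions yield their documented amino-acid consequences.
CODON_LOCKS: dict[int, str] = {
    4674: "ATT",   # ND2  Ile ->Val  on 4674 A>G (codon position 1)
    4794: "GGC",   # ND2  synonymous on 4796 C>T (position 3)
    5028: "ATG",   # ND2  Met ->Thr  on 5029 T>C (position 2)
    5142: "ATC",   # ND2  synonymous on 5144 C/T heteroplasmy (position 3)
    5910: "GCA",   # COX1 Ala ->Val  on 5911 C>T (position 2)
    7173: "ACA",   # COX1 synonymous on 7175 A>G (position 3)
    8542: "ATC",   # ATP6 frame: 8544 C>T synonymous Ile (position 3)
    8543: "TCA",   # ATP8 frame: 8544 C>T Ser->Leu (position 2)
    10080: "ATG",  # ND3  Met ->Thr  on 10081 T>C (position 2)
    10203: "ATC",  # ND3  synonymous on 10205 C>T (position 3)
    10398: "ACC",  # ND3  Thr ->Ala  on 10398 A>G (position 1)
    10784: "ATC",  # ND4  Ile ->Val  on 10784 A/G heteroplasmy (position 1)
    11024: "GGA",  # ND4  synonymous on 11026 A>G (position 3)
    11375: "CTG",  # ND4  synonymous on 11377 G>A (position 3)
    11777: "CGC",  # ND4  Arg ->His  on 11778 G>A (position 2)
    11912: "GGG",  # ND4  synonymous on 11914 G>A (position 3)
    12101: "GCC",  # ND4  synonymous on 12103 C>A (position 3)
    13708: "GCC",  # ND5  Ala ->Thr  on 13708 G>A (position 1)
    14798: "TTT",  # CYTB Phe ->Leu  on 14798 T>C (position 1)
    14831: "GCC",  # CYTB Ala ->Thr  on 14831 G>A (position 1)
    15173: "CTC",  # CYTB synonymous on 15175 C>T (position 3)
}

# Individual reference-strand base locks: minus-strand ND6 codons, rRNA /
# tRNA / control-region sites with a documented reference allele, and the
# rCRS placeholder N at 3107.
BASE_LOCKS: dict[int, str] = {
    # ND6 (minus strand): 14502 T>C = Ile->Val, 14668 C>T synonymous
    14500: "G", 14501: "A", 14502: "T",
    14668: "C", 14669: "C", 14670: "C",
    # ND2 site with a documented A (heteroplasmy 4992 A/G)
    4992: "A",
    # rRNA sites
    709: "G", 930: "G", 1719: "G", 3010: "G", 827: "A", 961: "T", 1820: "A",
    # tRNA sites
    4336: "T", 7476: "C", 7521: "G", 7561: "T", 10463: "T",
    12285: "T", 12308: "A", 15904: "C", 15924: "A", 15927: "G", 15928: "G",
    # control region
    150: "C", 16093: "T", 16182: "A", 16183: "A", 16286: "C", 16519: "T",
    # historical placeholder base
    3107: "N",
}

# tRNA secondary-structure domain assignments documented for specific sites;
# the remainder of each gene is filled with a sequential five-domain layout.
DOMAIN_OVERRIDES: dict[int, str] = {
    4336: "Acceptor stem",
    7476: "Anticodon stem",
    7521: "Acceptor stem",
    7561: "Variable loop",
    10463: "Acceptor stem",
    12285: "DHU loop",
    12308: "Variable loop",
    15904: "DHU loop",
    15927: "Anticodon stem",
    15928: "Anticodon stem",
}

TRNA_DOMAINS = ("Acceptor stem", "DHU loop", "Anticodon stem", "Variable loop", "TPsiC arm")

_STOPS = {"TAA", "TAG", "AGA", "AGG"}
_BASES = "ACGT"


def _annotations() -> list[GeneAnnotation]:
    return [
        GeneAnnotation(g, t, s, e, strand, 0, g if t == "tRNA" else "")
        for g, t, s, e, strand in GENE_TABLE
    ]


def _domain_maps() -> dict[str, dict[int, str]]:
    maps: dict[str, dict[int, str]] = {}
    for gene, ftype, start, end, _ in GENE_TABLE:
        if ftype != "tRNA":
            continue
        span = end - start + 1
        table = {}
        for i in range(span):
            table[start + i] = TRNA_DOMAINS[min(i * 5 // span, 4)]
        for pos, dom in DOMAIN_OVERRIDES.items():
            if start <= pos <= end:
                table[pos] = dom
        maps[gene] = table
    return maps


def _write_protein_genes(seq: list[str], locked: np.ndarray, ref: ReferenceModel,
                         rng: np.random.Generator) -> None:
    """Fill protein spans with stop-free codons that honour locked bases."""
    def set_codon(ann: GeneAnnotation, number: int, force_stop: bool) -> None:
        positions = ref.codon_positions(ann, number)
        fixed = {
            i: (COMPLEMENT[seq[p - 1]] if ann.strand == "-" else seq[p - 1])
            for i, p in enumerate(positions)
            if locked[p - 1]
        }
        pool = sorted(_STOPS) if force_stop else [
            a + b + c for a in _BASES for b in _BASES for c in _BASES
            if a + b + c not in _STOPS
        ]
        candidates = [c for c in pool if all(c[i] == b for i, b in fixed.items())]
        if not candidates:  # locked bases contradict the request; leave as-is
            return
        codon = candidates[rng.integers(len(candidates))]
        for i, p in enumerate(positions):
            if not locked[p - 1]:
                seq[p - 1] = COMPLEMENT[codon[i]] if ann.strand == "-" else codon[i]
                locked[p - 1] = True

    for ann in ref.protein_genes():
        n = ref.n_codons(ann)
        complete = (ann.length - ann.frame) % 3 == 0
        first = ref.codon_positions(ann, 1)
        if not any(locked[p - 1] for p in first):
            set_codon(ann, 1, force_stop=False)
            for i, p in enumerate(first):  # start codon where unconstrained
                seq[p - 1] = COMPLEMENT["ATG"[i]] if ann.strand == "-" else "ATG"[i]
        for number in range(1, n):
            set_codon(ann, number, force_stop=False)
        set_codon(ann, n, force_stop=complete)


def _repair_internal_stops(seq: list[str], hard_locked: np.ndarray,
                           ref: ReferenceModel, rng: np.random.Generator) -> None:
    """Remove internal stop codons without touching hard-locked bases.

    Overlapping reading frames (ATP8/ATP6, ND4L/ND4, ATP6/COX3) can reinstate
    a stop in the other frame, so iterate to a fixed point.
    """
    proteins = ref.protein_genes()
    for _ in range(300):
        ref.sequence = "".join(seq)  # refresh codon views
        dirty = False
        for ann in proteins:
            for number in range(1, ref.n_codons(ann)):  # internal codons only
                codon = ref.codon(ann, number)
                if codon not in _STOPS or "N" in codon:
                    continue
                positions = ref.codon_positions(ann, number)
                free = [i for i, p in enumerate(positions) if not hard_locked[p - 1]]
                if not free:
                    raise RuntimeError(f"unrepairable stop in {ann.gene}")
                i = free[-1]
                current = codon[i]
                choices = [b for b in _BASES if b != current]
                new = choices[rng.integers(3)]
                if ann.strand == "-":
                    new = COMPLEMENT[new]
                seq[positions[i] - 1] = new
                dirty = True
        if not dirty:
            return
    raise RuntimeError("stop-codon repair did not converge")


def build_reference() -> ReferenceModel:
    """Deterministically build the bundled synthetic rCRS-like reference."""
    rng = np.random.default_rng(_SEED)
    seq = list(rng.choice(list(_BASES), size=LENGTH))
    locked = np.zeros(LENGTH, dtype=bool)

    for start, codon in CODON_LOCKS.items():
        for i, b in enumerate(codon):
            seq[start - 1 + i] = b
            locked[start - 1 + i] = True
    for pos, b in BASE_LOCKS.items():
        seq[pos - 1] = b
        locked[pos - 1] = True
    hard_locked = locked.copy()

    ref = ReferenceModel(
        name="rCRS-like-synthetic",
        sequence="".join(seq),
        annotations=_annotations(),
        coding_range=CODING_RANGE,
        domain_maps=_domain_maps(),
    )
    _write_protein_genes(seq, locked, ref, rng)
    _repair_internal_stops(seq, hard_locked, ref, rng)
    ref.sequence = "".join(seq)

    for ann in ref.protein_genes():  # build-time sanity: frames are clean
        for number in range(1, ref.n_codons(ann)):
            codon = ref.codon(ann, number)
            assert "N" in codon or translate_codon(codon) != "*", (ann.gene, number)
    return ref


_CACHE: ReferenceModel | None = None


def load_rcrs_like() -> ReferenceModel:
    """Cached accessor for the bundled synthetic reference."""
    global _CACHE
    if _CACHE is None:
        _CACHE = build_reference()
    return _CACHE
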