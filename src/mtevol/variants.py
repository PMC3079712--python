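"""Variant shorthand parsing and hotspot masking.

Profiles use the compact forensic/phylogenetic shorthand for rCRS-relative
variants: a bare position is a transition (the alt allele is implied by the
reference base, A<->G / C<->T); a base suffix is a transversion; ``d`` a
deletion (``523-524d`` for a range); ``POS+SEQ`` an insertion; an IUPAC
ambiguity suffix (R/Y/S/W/K/M) a point heteroplasmy whose alt allele is the
non-reference base of the code; a ``@`` prefix marks a back mutation
(reversion towards the reference state).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

from .reference import (
    PURINES,
    PYRIMIDINES,
    TRANSITION_PARTNER,
    FormatError,
    ReferenceModel,
)

IUPAC_PAIRS = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}
PAIR_TO_IUPAC = {pair: code for code, pair in IUPAC_PAIRS.items()}

_TOKEN_RE = re.compile(
    r"""^(?P<back>@?)
        (?P<pos>\d+)
        (?:
            (?P<range>-(?P<pos2>\d+))?(?P<del>d)
          | \+(?P<count>\d*)(?P<ins>[ACGT]+)
          | (?P<suffix>[ACGTRYSWKM])
        )?$""",
    re.VERBOSE,
)


@dataclass(frozen=True)
class Variant:
    """One observed change relative to the circular reference."""

    position: int
    kind: str  # transition | transversion | deletion | insertion
    ref: str
    alt: str
    end: int | None = None  # last deleted position for range deletions
    heteroplasmic: bool = False
    back_mutation: bool = False

    @property
    def is_substitution(self) -> bool:
        return self.kind in ("transition", "transversion")

    @property
    def is_indel(self) -> bool:
        return self.kind in ("deletion", "insertion")

    def __str__(self) -> str:
        return format_variant(self)


def classify_substitution(ref: str | Variant, alt: str | None = None) -> str:
    """'transition' or 'transversion' by the purine/pyrimidine rule."""
    if isinstance(ref, Variant):
        v = ref
        if not v.is_substitution:
            raise ValueError(f"{v} is not a point substitution")
        ref, alt = v.ref, v.alt
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    same_family = ({ref, alt} <= PURINES) or ({ref, alt} <= PYRIMIDINES)
    return "transition" if same_family else "transversion"


def parse_variant(token: str, ref: ReferenceModel) -> Variant:
    """Parse one shorthand token against a reference model."""
    m = _TOKEN_RE.match(token.strip())
    if m is None:
        raise FormatError(f"unparseable variant token {token!r}")
    pos = int(m.group("pos"))
    if not 1 <= pos <= ref.length:
        raise FormatError(f"{token!r}: position {pos} outside 1..{ref.length}")
    back = bool(m.group("back"))

    if m.group("del"):
        end = int(m.group("pos2")) if m.group("pos2") else pos
        if end < pos or end > ref.length:
            raise FormatError(f"{token!r}: bad deletion range")
        deleted = "".join(ref.base(p) for p in range(pos, end + 1))
        return Variant(pos, "deletion", deleted, "-", end=end, back_mutation=back)

    if m.group("ins"):
        seq = m.group("ins")
        if m.group("count"):
            if len(seq) != 1:
                raise FormatError(f"{token!r}: repeat count needs a single base")
            seq = seq * int(m.group("count"))
        return Variant(pos, "insertion", ref.base(pos), seq, back_mutation=back)

    refbase = ref.base(pos)
    if refbase == "N":
        raise FormatError(f"{token!r}: reference base at {pos} is N")
    suffix = m.group("suffix")
    if suffix is None:  # plain transition
        return Variant(
            pos, "transition", refbase, TRANSITION_PARTNER[refbase], back_mutation=back
        )
    if suffix in IUPAC_PAIRS:  # point heteroplasmy
        pair = IUPAC_PAIRS[suffix]
        if refbase not in pair:
            raise FormatError(
                f"{token!r}: IUPAC code {suffix} does not include reference "
                f"base {refbase}"
            )
        alt = next(iter(pair - {refbase}))
        kind = classify_substitution(refbase, alt)
        return Variant(pos, kind, refbase, alt, heteroplasmic=True, back_mutation=back)
    # explicit base suffix: transversion by convention
    if suffix == refbase:
        raise FormatError(f"{token!r}: alt allele equals the reference base")
    if suffix == TRANSITION_PARTNER[refbase]:
        raise FormatError(
            f"{token!r}: explicit suffix equals the implied transition target; "
            f"write the bare position instead"
        )
    return Variant(pos, "transversion", refbase, suffix, back_mutation=back)


def format_variant(v: Variant) -> str:
    """Inverse of :func:`parse_variant` (round-trips grammar-valid tokens)."""
    at = "@" if v.back_mutation else ""
    if v.kind == "deletion":
        rng = f"{v.position}-{v.end}" if v.end and v.end != v.position else str(v.position)
        return f"{at}{rng}d"
    if v.kind == "insertion":
        return f"{at}{v.position}+{v.alt}"
    if v.heteroplasmic:
        return f"{at}{v.position}{PAIR_TO_IUPAC[frozenset((v.ref, v.alt))]}"
    if v.kind == "transition":
        return f"{at}{v.position}"
    return f"{at}{v.position}{v.alt}"


def strip_back_mutation(v: Variant) -> Variant:
    return replace(v, back_mutation=False) if v.back_mutation else v


# --- hotspot masking ------------------------------------------------------


class HotspotMask:
    """Mutational-hotspot exclusion rules for phylogenetic reconstruction.

    A mask is a plain-text configuration, one rule per line:

    ``LO-HI``            any variant whose span overlaps the position range
    ``POS``              any variant at POS
    ``POS+``             any insertion at POS
    ``POSd`` / ``POSB``  that exact token
    ``:heteroplasmy``    every point/length heteroplasmy

    Masking is idempotent and is applied to tree building only by default
    (heteroplasmies in particular are still reported by the triage stage).
    """

    def __init__(self, rules: Iterable[str] = ()):
        self.ranges: list[tuple[int, int]] = []
        self.positions: set[int] = set()
        self.insertion_sites: set[int] = set()
        self.exact_tokens: set[str] = set()
        self.mask_heteroplasmies = False
        self.rules: list[str] = []
        for rule in rules:
            self.add_rule(rule)

    def add_rule(self, rule: str) -> None:
        rule = rule.strip()
        if not rule or rule.startswith("#"):
            return
        self.rules.append(rule)
        if rule == ":heteroplasmy":
            self.mask_heteroplasmies = True
        elif re.fullmatch(r"\d+-\d+", rule):
            lo, hi = (int(x) for x in rule.split("-"))
            self.ranges.append((lo, hi))
        elif re.fullmatch(r"\d+", rule):
            self.positions.add(int(rule))
        elif re.fullmatch(r"\d+\+", rule):
            self.insertion_sites.add(int(rule[:-1]))
        else:
            self.exact_tokens.add(rule)

    @classmethod
    def from_file(cls, path: str | Path) -> "HotspotMask":
        return cls(Path(path).read_text().splitlines())

    @classmethod
    def empty(cls) -> "HotspotMask":
        return cls()

    def masks(self, v: Variant) -> bool:
        if self.mask_heteroplasmies and v.heteroplasmic:
            return True
        span_end = v.end or v.position
        for lo, hi in self.ranges:
            if v.position <= hi and span_end >= lo:
                return True
        if v.position in self.positions:
            return True
        if v.kind == "insertion" and v.position in self.insertion_sites:
            return True
        return format_variant(strip_back_mutation(v)) in self.exact_tokens


def apply_mask(
    variants: Iterable[Variant], mask: HotspotMask
) -> tuple[list[Variant], list[Variant]]:
    """Split variants into (kept, removed-by-mask)."""
    kept, removed = [], []
    for v in variants:
        (removed if mask.masks(v) else kept).append(v)
    return kept, removed
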