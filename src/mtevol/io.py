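"""Profile reading/writing and shared format helpers.

A profiles table is TSV with a header ``sample_id<TAB>carrier<TAB>variants``:
one sample per row, ``carrier`` flagging nuclear-mutation carrier status
(1/0, empty or '?' when unknown), and ``variants`` holding the
whitespace-separated shorthand tokens of all differences from the
reference.  Comment lines start with '#'.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .reference import FormatError, ReferenceModel
from .variants import HotspotMask, Variant, format_variant, parse_variant


@dataclass
class Profile:
    """One sample's variant list plus metadata."""

    sample_id: str
    variants: list[Variant]
    carrier: bool | None = None  # nuclear-mutation carrier flag

    def tokens(self, mask: HotspotMask | None = None) -> set[str]:
        """Shorthand tokens, optionally hotspot-masked (for tree building)."""
        out = set()
        for v in self.variants:
            if mask is not None and mask.masks(v):
                continue
            out.add(format_variant(v))
        return out

    @property
    def stratum(self) -> str:
        if self.carrier is None:
            return "unknown"
        return "carrier" if self.carrier else "non-carrier"


@dataclass
class ProfileError:
    sample_id: str
    token: str
    message: str


def read_profiles(
    tsv_path: str | Path,
    ref: ReferenceModel,
    mask: HotspotMask | None = None,
    strict: bool = True,
) -> tuple[list[Profile], list[ProfileError]]:
    """Parse and validate a profiles table.

    Per-token parse failures are collected as :class:`ProfileError`; with
    ``strict`` (default) any error raises.  Duplicate sample ids always
    raise.  ``mask`` is *not* applied here — profiles keep every token and
    downstream stages request masked views.
    """
    profiles: list[Profile] = []
    errors: list[ProfileError] = []
    seen: set[str] = set()
    lines = Path(tsv_path).read_text().splitlines()
    if not lines or not lines[0].lstrip("#").strip().startswith("sample_id"):
        # tolerate a leading provenance block before the header
        header_idx = next(
            (i for i, l in enumerate(lines) if l.startswith("sample_id\t")), None
        )
        if header_idx is None:
            raise FormatError(f"{tsv_path}: missing profiles header")
        lines = lines[header_idx:]
    for raw in lines[1:]:
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) < 3:
            fields += [""] * (3 - len(fields))
        sample_id, carrier_s, token_s = fields[0], fields[1], fields[2]
        if sample_id in seen:
            raise FormatError(f"duplicate sample id {sample_id!r}")
        seen.add(sample_id)
        carrier = {"1": True, "0": False}.get(carrier_s.strip())
        variants: list[Variant] = []
        for token in token_s.split():
            try:
                variants.append(parse_variant(token, ref))
            except FormatError as exc:
                errors.append(ProfileError(sample_id, token, str(exc)))
        profiles.append(Profile(sample_id, variants, carrier))
    if strict and errors:
        details = "; ".join(f"{e.sample_id}:{e.token}" for e in errors[:5])
        raise FormatError(f"{len(errors)} bad token(s) in {tsv_path}: {details}")
    _ = mask  # kept for signature compatibility; masking is downstream
    return profiles, errors


def write_profiles(profiles: list[Profile], path: str | Path,
                   header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("sample_id\tcarrier\tvariants\n")
        for p in profiles:
            carrier = "" if p.carrier is None else str(int(p.carrier))
            toks = " ".join(
                format_variant(v)
                for v in sorted(p.variants, key=lambda v: v.position)
            )
            fh.write(f"{p.sample_id}\t{carrier}\t{toks}\n")


def profiles_from_tokens(
    token_map: dict[str, list[str]], ref: ReferenceModel,
    carriers: dict[str, bool] | None = None,
) -> list[Profile]:
    """Build Profile objects from raw token lists (e.g. simulator output)."""
    out = []
    for sample_id, tokens in token_map.items():
        variants = [parse_variant(t, ref) for t in tokens]
        carrier = carriers.get(sample_id) if carriers else None
        out.append(Profile(sample_id, variants, carrier))
    return out
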