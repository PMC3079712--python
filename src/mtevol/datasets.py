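"""Accessors for the bundled knowledge tables and fixtures.

Everything here is a small, versioned, plain-text stand-in for external
resources (worldwide positional rates, known-variant catalogues, tRNA
conservation classes, a minimal reference haplogroup tree and a partial
study cohort); production analyses supply their own full tables through the
same readers.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .evocontext import ConservationTable, KnownVariantCatalogue, RateTable
from .haplotree import HaploTree, parse_haplotree
from .io import Profile, read_profiles
from .rcrs_like import load_rcrs_like
from .reference import ReferenceModel
from .variants import HotspotMask


def _path(name: str) -> Path:
    return Path(resources.files("mtevol.data") / name)


def bundled_mask() -> HotspotMask:
    """Hotspot exclusion list used for phylogenetic reconstruction."""
    return HotspotMask.from_file(_path("hotspot_mask.txt"))


def bundled_rates() -> RateTable:
    """Worldwide positional mutation-rate hit counts (worked-example rows)."""
    return RateTable.from_file(_path("soares_rates.tsv"))


def bundled_catalogue() -> KnownVariantCatalogue:
    return KnownVariantCatalogue.from_file(_path("known_variants.tsv"))


def bundled_conservation() -> ConservationTable:
    return ConservationTable.from_file(_path("trna_conservation.tsv"))


def bundled_phylotree() -> HaploTree:
    return parse_haplotree(_path("phylotree_mini.txt").read_text())


def bundled_reference() -> ReferenceModel:
    """The synthetic rCRS-like reference (see :mod:`mtevol.rcrs_like`)."""
    return load_rcrs_like()


def bundled_cohort() -> list[Profile]:
    """Partial transcription of the 45-genome study cohort.

    Only the per-sample variants documented in the published summary tables
    (recurrent, tRNA, private and heteroplasmic variants) plus each
    lineage's haplogroup-defining path are included; the remaining private
    variation of the cohort was not published per sample.
    """
    profiles, _ = read_profiles(_path("study_cohort_partial.tsv"),
                                bundled_reference())
    return profiles


def data_path(name: str) -> Path:
    """Filesystem path of a bundled data file (for CLI use)."""
    return _path(name)
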