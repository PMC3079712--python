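"""End-to-end analysis pipeline tying all stages together.

``run_pipeline`` takes a :class:`RunConfig` pointing at the input files and
produces the full report bundle: haplogroup calls, the hotspot-masked
backbone parsimony tree (newick + per-edge events table), spectrum reports
(total and per carrier stratum), the case-control haplogroup frequency
comparison, evolutionary-context tables (novelty, heteroplasmy triage) and
a provenance block.  Any stage failure aborts with a stage-named error and
removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotate import annotate_variant, figure_label
from .evocontext import (
    KnownVariantCatalogue,
    RateTable,
    triage_heteroplasmies,
    write_novelty_table,
    write_triage,
)
from .haplocall import (
    HaplogroupCall,
    call_haplogroup,
    compare_frequencies,
    load_control_counts,
    write_calls,
)
from .haplotree import load_haplotree
from .io import Profile, read_profiles
from .mptree import build_mp_tree, partition_variants, to_newick, write_events_table
from .reference import ReferenceModel, load_reference
from .spectrum import tabulate_spectrum
from .variants import HotspotMask, parse_variant


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    reference_fasta: str
    annotation_tsv: str
    haplotree: str
    profiles: str
    out_dir: str
    domain_tsv: str | None = None
    mask: str | None = None
    rate_table: str | None = None
    catalogue: str | None = None
    control_counts: str | None = None
    region: tuple[int, int] | None = None  # None = reference coding range
    counting: str = "events"
    yates_correction: bool = False
    alpha: float = 0.05
    seed: int = 0

    def existing_inputs(self) -> list[str]:
        paths = [self.reference_fasta, self.annotation_tsv, self.haplotree,
                 self.profiles, self.domain_tsv, self.mask, self.rate_table,
                 self.catalogue, self.control_counts]
        return [p for p in paths if p]


@dataclass
class PipelineResult:
    reference: ReferenceModel
    profiles: list[Profile]
    calls: dict[str, HaplogroupCall]
    tree: object
    partition: object
    report: object  # SpectrumReport (whole region filter)
    triage: list
    outputs: list[Path] = field(default_factory=list)


def _provenance(config: RunConfig) -> str:
    lines = [f"# mtevol={__version__}", f"# seed={config.seed}"]
    for p in config.existing_inputs():
        digest = hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]
        lines.append(f"# input={Path(p).name} sha256={digest}")
    for key in ("region", "counting", "yates_correction", "alpha"):
        lines.append(f"# {key}={getattr(config, key)}")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> PipelineResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def out(name: str) -> Path:
        p = out_dir / name
        written.append(p)
        return p

    missing = [p for p in config.existing_inputs() if not Path(p).exists()]
    if missing:
        raise PipelineError("config", FileNotFoundError(", ".join(missing)))

    try:
        stage = "load-reference"
        ref = load_reference(config.reference_fasta, config.annotation_tsv,
                             config.domain_tsv)
        mask = (HotspotMask.from_file(config.mask) if config.mask
                else HotspotMask.empty())
        tree_ref = load_haplotree(config.haplotree)

        stage = "read-profiles"
        profiles, _ = read_profiles(config.profiles, ref, strict=True)

        stage = "haplogroup-calling"
        calls = {
            p.sample_id: call_haplogroup(p.sample_id, p.tokens(mask), tree_ref)
            for p in profiles
        }
        write_calls(list(calls.values()), out("calls.tsv"))

        stage = "parsimony-tree"
        token_sets = {p.sample_id: p.tokens(mask) for p in profiles}
        mp = build_mp_tree(token_sets, tree_ref, calls)
        out("tree.nwk").write_text(to_newick(mp) + "\n")
        partition = partition_variants(mp)

        stage = "annotation"
        annotations = {}
        for ev in partition.events:
            key = ev.token.lstrip("@")
            if key not in annotations:
                annotations[key] = annotate_variant(parse_variant(key, ref), ref)
        labels = {t: figure_label(a) for t, a in annotations.items()}
        write_events_table(partition, labels, out("events.tsv"))

        stage = "spectrum"
        region = config.region or ref.coding_range
        strata = {p.sample_id: p.stratum for p in profiles}
        report = tabulate_spectrum(mp, annotations, partition, region=region,
                                   counting=config.counting, strata=strata)
        summary = {"total": report.summary(ref)}
        for label in sorted({s for s in strata.values() if s != "unknown"}):
            summary[label] = report.stratum(label).summary(ref)
        out("spectrum.json").write_text(
            _provenance(config) + json.dumps(summary, indent=1, sort_keys=True) + "\n"
        )
        report.to_tsv(out("spectrum.tsv"))

        stage = "frequency-comparison"
        if config.control_counts:
            controls = load_control_counts(config.control_counts)
            comp = compare_frequencies(list(calls.values()), controls, tree_ref,
                                       alpha=config.alpha)
            with open(out("frequency.tsv"), "w") as fh:
                fh.write(_provenance(config))
                fh.write(f"# bonferroni_threshold={comp.bonferroni_threshold:.6g}\n")
                comp.table.to_csv(fh, sep="\t", index=False)

        stage = "evolutionary-context"
        rates = (RateTable.from_file(config.rate_table) if config.rate_table
                 else RateTable(hits={}))
        catalogue = (KnownVariantCatalogue.from_file(config.catalogue)
                     if config.catalogue else KnownVariantCatalogue())
        full_profiles = {p.sample_id: p.variants for p in profiles}
        triage = triage_heteroplasmies(full_profiles, rates, catalogue, ref)
        write_triage(triage, out("triage.tsv"))
        private_tokens = sorted(
            {t for ev in partition.events if ev.status == "private"
             for t in [ev.token] if not t.startswith("@")},
        )
        private_variants = [parse_variant(t, ref) for t in private_tokens]
        write_novelty_table(private_variants, catalogue, rates, ref,
                            out("novelty.tsv"))

        stage = "provenance"
        out("provenance.txt").write_text(_provenance(config))
    except PipelineError:
        raise
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc

    return PipelineResult(
        reference=ref, profiles=profiles, calls=calls, tree=mp,
        partition=partition, report=report, triage=triage, outputs=written,
    )
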