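"""Synthetic cohort generator with exported ground truth.

Generates the full input bundle the pipeline consumes — a circular reference
with a protein/tRNA/rRNA/control-region layout (valid reading frames, no
internal stops), a parametric haplogroup tree, and cohorts with per-site
rate heterogeneity (baseline + hotspot multipliers), Poisson private
mutations with a transition:transversion bias and an optional
replacement-filtering step, plus injected heteroplasmies.  Everything is
drawn from one seeded generator stream, so identical configurations produce
byte-identical outputs, and mutations are drawn on the actual reference
sequence so synonymous/nonsynonymous ground truth is exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotate import annotate_variant
from .haplotree import HaploNode, HaploTree
from .reference import TRANSITION_PARTNER, GeneAnnotation, ReferenceModel, translate_codon
from .variants import PAIR_TO_IUPAC, parse_variant

_STOPS = {"TAA", "TAG", "AGA", "AGG"}
_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults emulate the data regime of a 45-genome clinical cohort drawn
    from common continental haplogroups: a few private variants per sample,
    a strong transition bias, rare recurrences concentrated at hotspot
    sites, and occasional point heteroplasmies.
    """

    seed: int = 0
    # reference layout
    genome_length: int = 12000
    control_length: int = 1000
    n_protein_genes: int = 6
    n_trna_genes: int = 8
    n_rrna_genes: int = 2
    trna_length: int = 70
    rrna_length: int = 600
    minus_strand_fraction: float = 0.25
    # haplogroup tree shape
    tree_depth: int = 3
    branching_factor: int = 3
    defining_variants_mean: float = 3.0
    back_mutation_prob: float = 0.03
    # cohort
    n_samples: int = 45
    haplogroup_freqs: dict[str, float] | None = None  # None = uniform over nodes
    private_mutation_mean: float = 3.0
    ts_tv_ratio: float = 17.6
    n_hotspots: int = 5
    hotspot_multiplier: float = 50.0
    heteroplasmy_prob: float = 0.13  # per sample
    nonsyn_keep_prob: float = 0.5  # replacement-filtering (selection) strength

    def validate(self) -> None:
        if self.control_length + 200 >= self.genome_length:
            raise ValueError("layout overflow: control region leaves no coding space")
        for name in ("private_mutation_mean", "ts_tv_ratio", "hotspot_multiplier"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.haplogroup_freqs is not None:
            total = sum(self.haplogroup_freqs.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"haplogroup frequencies sum to {total}, not 1")


@dataclass
class GroundTruth:
    """Generative truth for recovery testing."""

    haplogroup: dict[str, str] = field(default_factory=dict)  # sample -> hg
    private: dict[str, list[str]] = field(default_factory=dict)  # sample -> tokens
    heteroplasmies: dict[str, list[str]] = field(default_factory=dict)
    recurrent_positions: list[int] = field(default_factory=list)
    hotspot_positions: list[int] = field(default_factory=list)
    effects: dict[str, str] = field(default_factory=dict)  # token -> primary effect
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# --- reference simulation -------------------------------------------------


def _random_protein_codons(n: int, rng: np.random.Generator) -> str:
    pool = [a + b + c for a in _BASES for b in _BASES for c in _BASES
            if a + b + c not in _STOPS]
    body = "".join(pool[i] for i in rng.integers(len(pool), size=n - 2))
    return "ATG" + body + "TAA"


def simulate_reference(config: SimulationConfig) -> ReferenceModel:
    """Random reference with a gene layout fitting ``genome_length``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    head = config.control_length // 2
    tail = config.control_length - head
    coding_lo, coding_hi = head + 1, L - tail
    seq = list(rng.choice(list(_BASES), size=L))

    # budget the coding arc across the requested features
    features: list[tuple[str, str, int]] = []  # (name, type, length)
    for i in range(config.n_rrna_genes):
        features.append((f"rrnS{i+1}", "rRNA", config.rrna_length))
    space = coding_hi - coding_lo + 1
    fixed = sum(f[2] for f in features) + config.n_trna_genes * config.trna_length
    spacers = config.n_protein_genes + config.n_trna_genes + config.n_rrna_genes + 1
    protein_budget = space - fixed - 2 * spacers
    if protein_budget < 90 * config.n_protein_genes:
        raise ValueError("layout overflow: genes do not fit the coding region")
    per_protein = protein_budget // config.n_protein_genes // 3 * 3
    order: list[tuple[str, str, int]] = []
    trna_i = prot_i = 0
    for slot in range(config.n_protein_genes + config.n_trna_genes):
        # interleave tRNAs between protein genes, as in real mtDNA
        if slot % 2 == 0 and trna_i < config.n_trna_genes:
            trna_i += 1
            order.append((f"tRNA-{trna_i}", "tRNA", config.trna_length))
        elif prot_i < config.n_protein_genes:
            prot_i += 1
            order.append((f"P{prot_i}", "protein", per_protein))
        elif trna_i < config.n_trna_genes:
            trna_i += 1
            order.append((f"tRNA-{trna_i}", "tRNA", config.trna_length))
    order = features + order

    annotations: list[GeneAnnotation] = []
    cursor = coding_lo
    for name, ftype, length in order:
        start = cursor + int(rng.integers(0, 3))
        end = start + length - 1
        if end > coding_hi:
            raise ValueError("layout overflow while placing genes")
        strand = "+"
        if ftype in ("protein", "tRNA") and rng.random() < config.minus_strand_fraction:
            strand = "-"
        annotations.append(
            GeneAnnotation(name, ftype, start, end, strand, 0,
                           name if ftype == "tRNA" else "")
        )
        cursor = end + 1

    ref = ReferenceModel(
        name=f"synthetic-mt-{config.seed}",
        sequence="".join(seq),
        annotations=annotations,
        coding_range=(coding_lo, coding_hi),
    )
    for ann in ref.protein_genes():
        codons = _random_protein_codons(ref.n_codons(ann), rng)
        for number in range(1, ref.n_codons(ann) + 1):
            codon = codons[3 * (number - 1) : 3 * number]
            for i, p in enumerate(ref.codon_positions(ann, number)):
                seq[p - 1] = codon[i] if ann.strand == "+" else \
                    {"A": "T", "T": "A", "C": "G", "G": "C"}[codon[i]]
    ref.sequence = "".join(seq)
    # five-segment tRNA domain maps
    domains = ("Acceptor stem", "DHU loop", "Anticodon stem", "Variable loop", "TPsiC arm")
    for ann in ref.annotations:
        if ann.feature_type == "tRNA":
            ref.domain_maps[ann.domain_map_id] = {
                ann.start + i: domains[min(i * 5 // ann.length, 4)]
                for i in range(ann.length)
            }
    return ref


# --- site rate model ------------------------------------------------------


def _site_weights(config: SimulationConfig, ref: ReferenceModel,
                  rng: np.random.Generator) -> tuple[np.ndarray, list[int]]:
    weights = np.ones(ref.length)
    lo, hi = ref.coding_range
    hotspots = sorted(
        int(p) for p in rng.choice(np.arange(lo, hi + 1),
                                   size=config.n_hotspots, replace=False)
    )
    for p in hotspots:
        weights[p - 1] *= config.hotspot_multiplier
    for i, b in enumerate(ref.sequence):
        if b == "N":
            weights[i] = 0.0
    return weights / weights.sum(), hotspots


def _draw_token(ref: ReferenceModel, weights: np.ndarray, used: set[int],
                config: SimulationConfig, rng: np.random.Generator,
                effect_filter: bool) -> str:
    """One substitution token at a rate-weighted site not already used."""
    p_ts = config.ts_tv_ratio / (config.ts_tv_ratio + 1.0)
    for _ in range(1000):
        pos = int(rng.choice(ref.length, p=weights)) + 1
        if pos in used:
            continue
        refbase = ref.base(pos)
        if refbase == "N":
            continue
        if rng.random() < p_ts:
            token = str(pos)
        else:
            options = [b for b in _BASES
                       if b not in (refbase, TRANSITION_PARTNER[refbase])]
            token = f"{pos}{options[rng.integers(2)]}"
        if effect_filter and config.nonsyn_keep_prob < 1.0:
            ann = annotate_variant(parse_variant(token, ref), ref)
            if ann.primary.effect in ("nonsynonymous", "stop") and \
                    rng.random() > config.nonsyn_keep_prob:
                continue  # purged by selection; redraw
        used.add(pos)
        return token
    raise RuntimeError("could not place a mutation (site space exhausted)")


# --- tree and cohort ------------------------------------------------------


def simulate_haplotree(config: SimulationConfig, ref: ReferenceModel,
                       rng: np.random.Generator,
                       weights: np.ndarray) -> HaploTree:
    """Parametric rooted haplogroup tree with rate-weighted defining tokens."""
    counter = [0]

    def grow(parent: HaploNode, depth: int, path_positions: set[int],
             path_tokens: list[str]) -> None:
        if depth >= config.tree_depth:
            return
        for _ in range(config.branching_factor):
            counter[0] += 1
            name = f"HG{counter[0]}"
            k = max(1, int(rng.poisson(config.defining_variants_mean)))
            local_positions = set(path_positions)
            tokens: list[str] = []
            cancellable = [t for t in path_tokens if not t.startswith("@")
                           and t.isdigit()]
            for _ in range(k):
                if cancellable and rng.random() < config.back_mutation_prob:
                    target = cancellable[rng.integers(len(cancellable))]
                    token = f"@{target}"
                    cancellable.remove(target)
                else:
                    token = _draw_token(ref, weights, local_positions, config,
                                        rng, effect_filter=True)
                tokens.append(token)
            node = HaploNode(name, tokens, parent=parent)
            parent.children.append(node)
            cancelled = {t[1:] for t in tokens if t.startswith("@")}
            child_path = [t for t in path_tokens if t not in cancelled]
            child_path += [t for t in tokens if not t.startswith("@")]
            grow(node, depth + 1, local_positions, child_path)

    root = HaploNode("ROOT", [])
    grow(root, 0, set(), [])
    return HaploTree(root)


def simulate_cohort(
    config: SimulationConfig, ref: ReferenceModel
) -> tuple[dict[str, list[str]], HaploTree, GroundTruth]:
    """Profiles (sample -> token list), haplogroup tree and ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    weights, hotspots = _site_weights(config, ref, rng)
    tree = simulate_haplotree(config, ref, rng, weights)

    names = [n.name for n in tree.walk() if n is not tree.root]
    if config.haplogroup_freqs is not None:
        missing = set(config.haplogroup_freqs) - set(names) - {tree.root.name}
        if missing:
            raise ValueError(f"frequency vector names absent from tree: {missing}")
        names = list(config.haplogroup_freqs)
        probs = np.array([config.haplogroup_freqs[n] for n in names])
    else:
        probs = np.full(len(names), 1.0 / len(names))

    truth = GroundTruth(seed=config.seed)
    profiles: dict[str, list[str]] = {}
    position_contexts: dict[int, set[str]] = {}

    for name in tree.nodes:  # tree events count as one context per branch
        for t in tree.nodes[name].tokens:
            pos = int(t.lstrip("@").rstrip("ACGT"))
            position_contexts.setdefault(pos, set()).add(f"branch:{name}")

    for i in range(config.n_samples):
        sample = f"S{i+1:03d}"
        hg = names[int(rng.choice(len(names), p=probs))]
        path = tree.cumulative_tokens(hg)
        used = {int(t.rstrip("ACGT")) for t in path}
        privates: list[str] = []
        for _ in range(int(rng.poisson(config.private_mutation_mean))):
            token = _draw_token(ref, weights, used, config, rng, effect_filter=True)
            privates.append(token)
            position_contexts.setdefault(int(token.rstrip("ACGT")), set()).add(
                f"private:{sample}"
            )
        hets: list[str] = []
        if rng.random() < config.heteroplasmy_prob:
            for _ in range(100):
                pos = int(rng.choice(ref.length, p=weights)) + 1
                refbase = ref.base(pos)
                if pos in used or refbase == "N":
                    continue
                code = PAIR_TO_IUPAC[frozenset((refbase, TRANSITION_PARTNER[refbase]))]
                hets.append(f"{pos}{code}")
                used.add(pos)
                break
        tokens = sorted(path | set(privates) | set(hets),
                        key=lambda t: int(t.lstrip("@").rstrip("ACGTRYSWKM")))
        profiles[sample] = tokens
        truth.haplogroup[sample] = hg
        truth.private[sample] = sorted(privates)
        truth.heteroplasmies[sample] = sorted(hets)
        for t in privates:
            truth.effects[t] = annotate_variant(
                parse_variant(t, ref), ref
            ).primary.effect or "non-coding"

    truth.hotspot_positions = hotspots
    truth.recurrent_positions = sorted(
        pos for pos, ctx in position_contexts.items() if len(ctx) >= 2
    )
    return profiles, tree, truth


# --- recovery metrics -----------------------------------------------------


@dataclass
class RecoveryReport:
    haplogroup_accuracy: float
    private_precision: float
    private_recall: float
    recurrent_sensitivity: float
    recurrent_specificity: float
    heteroplasmy_detection_rate: float

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def recovery_report(
    calls: dict[str, str],
    extras: dict[str, set[str]],
    detected_recurrent: set[int],
    detected_heteroplasmies: set[tuple[int, frozenset[str]]],
    truth: GroundTruth,
    genome_length: int,
) -> RecoveryReport:
    """Score pipeline outputs against generative truth."""
    if set(calls) != set(truth.haplogroup):
        raise ValueError("sample ids of calls and truth do not match")
    n = len(calls)
    acc = sum(calls[s] == truth.haplogroup[s] for s in calls) / n

    tp = fp = fn = 0
    for s in calls:
        true_set = set(truth.private[s])
        # back mutations and heteroplasmy tokens are scored elsewhere
        got = {
            t for t in extras.get(s, set())
            if not t.startswith("@") and t[-1] not in "RYSWKM"
        }
        tp += len(got & true_set)
        fp += len(got - true_set)
        fn += len(true_set - got)
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0

    true_rec = set(truth.recurrent_positions)
    rec_tp = len(detected_recurrent & true_rec)
    sens = rec_tp / len(true_rec) if true_rec else 1.0
    neg = genome_length - len(true_rec)
    spec = 1.0 - len(detected_recurrent - true_rec) / neg if neg else 1.0

    injected: set[tuple[int, frozenset[str]]] = set()
    for s, toks in truth.heteroplasmies.items():
        for t in toks:
            pos = int(t[:-1])
            from .variants import IUPAC_PAIRS

            injected.add((pos, IUPAC_PAIRS[t[-1]]))
    het_rate = (
        len(detected_heteroplasmies & injected) / len(injected) if injected else 1.0
    )
    return RecoveryReport(acc, precision, recall, sens, spec, het_rate)
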