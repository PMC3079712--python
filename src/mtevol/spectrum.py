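"""Cohort-level mutation-spectrum statistics.

The counting unit is the *event*: one placed occurrence of a variant on a
tree edge (a recurrent position therefore contributes once per carrying
edge).  A distinct-variant counting mode is available as an option.  All
ratios and tests are recomputable from the underlying event table, which is
a plain DataFrame with one row per substitution event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import VariantAnnotation, figure_label
from .haplocall import bonferroni_threshold  # noqa: F401  (re-export)
from .mptree import MPNode, MPTree, VariantPartition
from .reference import ReferenceModel

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


class CoverageError(RuntimeError):
    """A placed event had no annotation (upstream bug guard)."""


@dataclass
class CorrelationResult:
    r: float
    r2: float
    n: int
    flagged: bool = False  # zero variance or too few genes


@dataclass
class Chi2Result:
    table: np.ndarray
    chi2: float | None
    p_value: float | None
    df: int = 1
    skipped: bool = False  # zero margin


def tabulate_spectrum(
    tree: MPTree,
    annotations: dict[str, VariantAnnotation],
    partition: VariantPartition,
    region: tuple[int, int] | None = None,
    counting: str = "events",
    strata: dict[str, str] | None = None,
) -> "SpectrumReport":
    """Build the event table for a region (default: whole molecule).

    ``annotations`` maps each distinct token (without the ``@`` prefix) to
    its annotation; an unannotated placed event raises
    :class:`CoverageError`.  ``strata`` optionally maps sample id to a
    stratum label; an edge's events inherit the common stratum of all its
    descendant tips, or 'mixed'.
    """
    if counting not in ("events", "variants"):
        raise ValueError(f"unknown counting mode {counting!r}")
    edge_stratum = _edge_strata(tree, strata) if strata is not None else {}

    rows, indel_rows, seen_tokens = [], [], set()
    for ev in partition.events:
        key = ev.token.lstrip("@")
        if counting == "variants":
            if key in seen_tokens:
                continue
            seen_tokens.add(key)
        ann = annotations.get(key)
        if ann is None:
            raise CoverageError(f"event {ev.token} on edge {ev.edge} lacks annotation")
        v = ann.variant
        if region is not None and not (region[0] <= ev.position <= region[1]):
            continue
        c = ann.primary
        row = {
            "token": ev.token,
            "position": ev.position,
            "edge": ev.edge,
            "haplogroup": ev.haplogroup,
            "status": ev.status,  # private (young) vs haplogroup-defining (old)
            "backbone": ev.backbone,
            "back_mutation": ev.token.startswith("@"),
            "kind": v.kind,
            "ref": v.ref,
            "alt": v.alt,
            "gene": c.gene,
            "region_class": c.region_class,
            "effect": c.effect,
            "codon_position": c.codon_position,
            "aa_from": c.aa_from,
            "aa_to": c.aa_to,
            "aa_class_change": c.aa_class_change,
            "viamt": c.viamt,
            "label": figure_label(ann),
            "stratum": edge_stratum.get(ev.edge, ""),
        }
        (rows if v.is_substitution else indel_rows).append(row)
    columns = [
        "token", "position", "edge", "haplogroup", "status", "backbone",
        "back_mutation", "kind", "ref", "alt", "gene", "region_class",
        "effect", "codon_position", "aa_from", "aa_to", "aa_class_change",
        "viamt", "label", "stratum",
    ]
    return SpectrumReport(
        events=pd.DataFrame(rows, columns=columns),
        indels=pd.DataFrame(indel_rows, columns=columns),
        region=region,
        counting=counting,
    )


def _edge_strata(tree: MPTree, strata: dict[str, str]) -> dict[str, str]:
    """Stratum of each edge: the common stratum of its descendant tips."""
    out: dict[str, str] = {}

    def descend(node: MPNode) -> set[str]:
        if node.is_tip:
            labels = {strata.get(node.name, "?")}
        else:
            labels = set()
            for child in node.children:
                labels |= descend(child)
        out[node.name] = labels.pop() if len(labels) == 1 else "mixed"
        return {out[node.name]} if out[node.name] != "mixed" else {"mixed"}

    descend(tree.root)
    return out


@dataclass
class SpectrumReport:
    events: pd.DataFrame
    indels: pd.DataFrame
    region: tuple[int, int] | None
    counting: str

    # --- headline counts --------------------------------------------------

    @property
    def n_substitution_events(self) -> int:
        return len(self.events)

    def restrict(self, mask: pd.Series) -> "SpectrumReport":
        return SpectrumReport(
            self.events[mask], self.indels, self.region, self.counting
        )

    def stratum(self, label: str) -> "SpectrumReport":
        return self.restrict(self.events["stratum"] == label)

    # --- substitution type ------------------------------------------------

    def ts_tv_counts(self) -> tuple[int, int]:
        k = self.events["kind"]
        return int((k == "transition").sum()), int((k == "transversion").sum())

    def ts_tv_ratio(self) -> float:
        ts, tv = self.ts_tv_counts()
        return np.inf if tv == 0 else ts / tv

    def tv_target_counts(self) -> dict[str, int]:
        tv = self.events[self.events["kind"] == "transversion"]
        return {b: int((tv["alt"] == b).sum()) for b in "AGCT"}

    def tv_spectrum(self) -> dict[str, int]:
        """Integer-normalised transversion target-base ratio A:G:C:T."""
        counts = self.tv_target_counts()
        positive = [n for n in counts.values() if n > 0]
        if not positive:
            return {b: 0 for b in "AGCT"}
        unit = min(positive)
        return {b: round(n / unit) for b, n in counts.items()}

    # --- protein-gene effects ---------------------------------------------

    def protein_events(self) -> pd.DataFrame:
        return self.events[self.events["region_class"] == "protein"]

    def effect_counts(self) -> dict[str, int]:
        prot = self.protein_events()
        return {
            e: int((prot["effect"] == e).sum())
            for e in ("synonymous", "nonsynonymous", "stop", "undetermined")
        }

    def ns_ratio(self) -> tuple[float, bool]:
        """(x, infinite_flag) for the nonsynonymous:synonymous ratio 1:x."""
        c = self.effect_counts()
        if c["nonsynonymous"] == 0:
            return np.inf, True
        return c["synonymous"] / c["nonsynonymous"], False

    def nonsynonymous_share(self) -> float:
        """Fraction of protein-gene substitution events that are replacements."""
        c = self.effect_counts()
        total = c["synonymous"] + c["nonsynonymous"] + c["stop"]
        return c["nonsynonymous"] / total if total else np.nan

    def codon_position_fractions(self) -> dict[int, float]:
        prot = self.protein_events().dropna(subset=["codon_position"])
        n = len(prot)
        return {
            p: (int((prot["codon_position"] == p).sum()) / n if n else np.nan)
            for p in (1, 2, 3)
        }

    # --- regions and genes -------------------------------------------------

    def region_counts(self) -> dict[str, int]:
        rc = self.events["region_class"]
        return {r: int((rc == r).sum()) for r in rc.unique()}

    def gene_counts(self, subset: str = "all") -> pd.Series:
        prot = self.protein_events()
        if subset in ("synonymous", "nonsynonymous"):
            prot = prot[prot["effect"] == subset]
        elif subset != "all":
            raise ValueError(f"unknown subset {subset!r}")
        return prot.groupby("gene").size()

    def gene_length_correlation(
        self, ref: ReferenceModel, subset: str = "all"
    ) -> CorrelationResult:
        """Pearson correlation of per-gene event counts vs gene length (bp);
        protein genes with zero events contribute zero counts."""
        counts = self.gene_counts(subset)
        genes = ref.protein_genes()
        if len(genes) < 3:
            raise ValueError("need >=3 protein genes for a correlation")
        x = np.array([g.length for g in genes], dtype=float)
        y = np.array([counts.get(g.gene, 0) for g in genes], dtype=float)
        if np.allclose(x.var(), 0) or np.allclose(y.var(), 0):
            return CorrelationResult(np.nan, np.nan, len(genes), flagged=True)
        r, _ = stats.pearsonr(x, y)
        return CorrelationResult(float(r), float(r * r), len(genes))

    # --- branch age -------------------------------------------------------

    def young_old_table(self) -> np.ndarray:
        """2x2 of (young=private, old=haplogroup-defining) x (ns, s)."""
        prot = self.protein_events()
        out = np.zeros((2, 2), dtype=int)
        for i, status in enumerate(("private", "haplogroup-defining")):
            sub = prot[prot["status"] == status]
            out[i, 0] = int((sub["effect"] == "nonsynonymous").sum())
            out[i, 1] = int((sub["effect"] == "synonymous").sum())
        return out

    def young_old_test(self, correction: bool = False) -> Chi2Result:
        table = self.young_old_table()
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            return Chi2Result(table, None, None, skipped=True)
        chi2, p, df, _ = stats.chi2_contingency(table, correction=correction)
        return Chi2Result(table, float(chi2), float(p), df=int(df))

    # --- amino-acid involvement -------------------------------------------

    def aa_hit_counts(self) -> pd.Series:
        """Per-amino-acid involvement in replacement events (from + to)."""
        prot = self.protein_events()
        ns = prot[prot["effect"] == "nonsynonymous"]
        hits = pd.Series(0, index=list(AA_ORDER), dtype=int)
        for col in ("aa_from", "aa_to"):
            vc = ns[col].value_counts()
            hits = hits.add(vc.reindex(hits.index, fill_value=0).astype(int), fill_value=0)
        return hits

    def aa_hit_ratio(self, group: tuple[str, ...] = ("T", "V")) -> float:
        """Mean per-amino-acid replacement involvement of ``group`` relative
        to the mean over the remaining amino acids."""
        hits = self.aa_hit_counts()
        inside = hits[list(group)].mean()
        outside = hits[[a for a in AA_ORDER if a not in group]].mean()
        return np.inf if outside == 0 else float(inside / outside)

    def aa_class_change_counts(self) -> pd.Series:
        ns = self.protein_events()
        ns = ns[ns["effect"] == "nonsynonymous"]
        return ns.groupby("aa_class_change").size().sort_values(ascending=False)

    def viamt_count(self) -> int:
        return int(self.protein_events()["viamt"].sum())

    # --- serialisation ----------------------------------------------------

    def summary(self, ref: ReferenceModel | None = None) -> dict:
        ts, tv = self.ts_tv_counts()
        eff = self.effect_counts()
        ns_x, ns_inf = self.ns_ratio()
        out = {
            "region": list(self.region) if self.region else None,
            "counting": self.counting,
            "substitution_events": self.n_substitution_events,
            "indel_events": int(len(self.indels)),
            "transitions": ts,
            "transversions": tv,
            "ts_tv_ratio": None if tv == 0 else round(ts / tv, 2),
            "tv_spectrum_AGCT": self.tv_spectrum(),
            "effect_counts": eff,
            "ns_ratio_1_to_x": None if ns_inf else round(ns_x, 2),
            "nonsynonymous_share": None
            if np.isnan(self.nonsynonymous_share())
            else round(self.nonsynonymous_share(), 4),
            "codon_position_fractions": {
                str(k): None if np.isnan(v) else round(v, 4)
                for k, v in self.codon_position_fractions().items()
            },
            "region_counts": self.region_counts(),
            "aa_hit_ratio_TV_vs_others": None,
            "viamt_replacements": self.viamt_count(),
            "young_old_table": self.young_old_table().tolist(),
        }
        if not self.protein_events().empty:
            ratio = self.aa_hit_ratio()
            out["aa_hit_ratio_TV_vs_others"] = (
                None if np.isinf(ratio) else round(ratio, 2)
            )
        yo = self.young_old_test()
        out["young_old_chi2"] = None if yo.skipped else round(yo.chi2, 4)
        out["young_old_p"] = None if yo.skipped else round(yo.p_value, 4)
        if ref is not None:
            for subset in ("all", "synonymous", "nonsynonymous"):
                try:
                    c = self.gene_length_correlation(ref, subset)
                    out[f"gene_length_r2_{subset}"] = (
                        None if c.flagged else round(c.r2, 4)
                    )
                except ValueError:
                    out[f"gene_length_r2_{subset}"] = None
        return out

    def to_tsv(self, path) -> None:
        """Flat (category, level, count) table."""
        rows = []
        for cat, counts in (
            ("effect", self.effect_counts()),
            ("region", self.region_counts()),
            ("tv_target", self.tv_target_counts()),
        ):
            rows.extend({"category": cat, "level": k, "count": v} for k, v in counts.items())
        kinds = self.events["kind"].value_counts().to_dict()
        rows.extend(
            {"category": "kind", "level": k, "count": v} for k, v in kinds.items()
        )
        cp = self.protein_events().dropna(subset=["codon_position"])
        for p in (1, 2, 3):
            rows.append(
                {"category": "codon_position", "level": p,
                 "count": int((cp["codon_position"] == p).sum())}
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
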