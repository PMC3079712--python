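"""Haplogroup assignment and case-control haplogroup frequency testing.

Each masked profile is scored against every node of the reference tree with
the linear score ``|matched| - |missing| - w*|extras|`` (w defaults to 0);
the winning node is the call, ties broken by depth (deeper wins) and then
name.  Observed-but-unexpected tokens are surfaced as candidate private
variants.  Cohort haplogroup frequencies are compared against control counts
category-by-category with Pearson's chi-square on 2x2 tables and a
Bonferroni-adjusted significance threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

from .haplotree import HaploTree
from .variants import HotspotMask


@dataclass
class HaplogroupCall:
    sample_id: str
    haplogroup: str
    score: float
    matched: set[str] = field(default_factory=set)
    missing: set[str] = field(default_factory=set)
    extras: set[str] = field(default_factory=set)


def _canonical_profile(tokens: set[str]) -> set[str]:
    """Apply profile-level back-mutation cancellation: P + @P annihilate."""
    out = set(tokens)
    for t in list(out):
        if t.startswith("@") and t[1:] in out:
            out.discard(t)
            out.discard(t[1:])
    return out


def call_haplogroup(
    sample_id: str,
    tokens: set[str] | list[str],
    tree: HaploTree,
    mask: HotspotMask | None = None,
    extras_weight: float = 0.0,
) -> HaplogroupCall:
    """Assign the best-scoring haplogroup to one masked profile.

    ``tokens`` are shorthand strings (already hotspot-masked upstream for
    tree building; any tokens matching mask rules by exact string are also
    ignored here, as are the corresponding defining tokens).
    """
    if not tree.nodes:
        raise ValueError("empty haplogroup tree")
    profile = _canonical_profile(set(tokens))
    best: tuple[float, int, str] | None = None
    best_call: HaplogroupCall | None = None
    for name in tree.nodes:
        path = tree.cumulative_tokens(name)
        matched = path & profile
        missing = path - profile
        extras = profile - path
        # lone profile-level back mutations that cancel a path variant:
        # "@P" in the profile removes P from the expected set
        for t in list(extras):
            if t.startswith("@") and t[1:] in missing:
                missing.discard(t[1:])
                extras.discard(t)
        score = len(matched) - len(missing) - extras_weight * len(extras)
        key = (score, tree.nodes[name].depth, _neg_lex(name))
        if best is None or key > best:
            best = key
            best_call = HaplogroupCall(
                sample_id, name, score, matched, missing, extras
            )
    assert best_call is not None
    return best_call


class _neg_lex(str):
    """Order wrapper: lexicographically *smaller* names win ties."""

    def __lt__(self, other: str) -> bool:  # type: ignore[override]
        return str(self) > str(other)

    def __gt__(self, other: str) -> bool:  # type: ignore[override]
        return str(self) < str(other)


def write_calls(calls: list[HaplogroupCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\thaplogroup\tscore\tmissing\textras\n")
        for c in calls:
            fh.write(
                f"{c.sample_id}\t{c.haplogroup}\t{c.score:g}\t"
                f"{' '.join(sorted(c.missing))}\t{' '.join(sorted(c.extras))}\n"
            )


# --- case-control frequency comparison ------------------------------------


@dataclass
class FrequencyComparison:
    """Per-category 2x2 chi-square results plus the Bonferroni threshold."""

    table: pd.DataFrame  # category, case_count, control_count, chi2, p_value
    alpha: float
    n_tests: int

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.n_tests

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p_value"] < self.bonferroni_threshold]


def aggregate_call(haplogroup: str, tree: HaploTree, categories: set[str]) -> str:
    """Category of a call = nearest labelled ancestor (inclusive)."""
    for node in reversed(tree.path_to(haplogroup)):
        if node.name in categories:
            return node.name
    return "other"


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) for [[a, b], [c, d]]."""
    stat, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    return float(stat), float(p)


def compare_frequencies(
    case_calls: list[HaplogroupCall],
    control_counts: dict[str, int],
    tree: HaploTree,
    alpha: float = 0.05,
) -> FrequencyComparison:
    """Compare cohort haplogroup-category frequencies against controls.

    ``control_counts`` keys define the category labels; every case call is
    assigned to the nearest labelled ancestor of its haplogroup (falling back
    to 'other').  Each category is tested with a 2x2 Pearson chi-square of
    in-category vs not-in-category counts.
    """
    categories = set(control_counts)
    case_cat = pd.Series(
        [aggregate_call(c.haplogroup, tree, categories) for c in case_calls]
    )
    n_cases = len(case_calls)
    n_controls = sum(control_counts.values())
    rows = []
    for cat in sorted(categories | set(case_cat.unique())):
        a = int((case_cat == cat).sum())
        c = int(control_counts.get(cat, 0))
        if a + c == 0:
            warnings.warn(f"category {cat!r} empty in both groups; excluded")
            continue
        chi2, p = pearson_chi2_2x2(a, n_cases - a, c, n_controls - c)
        rows.append(
            {"category": cat, "case_count": a, "control_count": c,
             "chi2": chi2, "p_value": p}
        )
    table = pd.DataFrame(rows)
    return FrequencyComparison(table=table, alpha=alpha, n_tests=len(rows))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Adjusted per-test significance threshold for m independent tests."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def load_control_counts(path: str | Path) -> dict[str, int]:
    counts: dict[str, int] = {}
    for raw in Path(path).read_text().splitlines():
        if not raw.strip() or raw.startswith("#") or raw.startswith("category\t"):
            continue
        cat, n = raw.split("\t")[:2]
        counts[cat] = int(n)
    return counts
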