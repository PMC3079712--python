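"""Mutation-spectrum statistics: counts, ratios, tests, correlations."""

import numpy as np
import pytest
from scipy import stats

from mtevol.annotate import annotate_variant
from mtevol.haplocall import call_haplogroup
from mtevol.mptree import build_mp_tree, partition_variants
from mtevol.spectrum import CoverageError, tabulate_spectrum
from mtevol.variants import parse_variant


def _report(rcrs, profiles, backbone, region=None, **kw):
    calls = {s: call_haplogroup(s, t, backbone) for s, t in profiles.items()}
    mp = build_mp_tree(profiles, backbone, calls)
    part = partition_variants(mp)
    anns = {
        ev.token.lstrip("@"): annotate_variant(
            parse_variant(ev.token.lstrip("@"), rcrs), rcrs
        )
        for ev in part.events
    }
    return tabulate_spectrum(mp, anns, part, region=region, **kw), mp, part


ROOT_ONLY_TEXT = "ROOT\n"


@pytest.fixture(scope="module")
def root_only():
    from mtevol.haplotree import parse_haplotree

    return parse_haplotree(ROOT_ONLY_TEXT)


def test_constructed_synonymous_only_profile(rcrs, root_only):
    # three synonymous third-position changes in ND4 / ND3 / CYTB
    profiles = {"S1": {"11377", "10205", "15175"}}
    report, _, _ = _report(rcrs, profiles, root_only)
    eff = report.effect_counts()
    assert eff["synonymous"] == 3 and eff["nonsynonymous"] == 0
    x, inf = report.ns_ratio()
    assert inf  # zero nonsynonymous is reported as infinite with a flag
    assert report.codon_position_fractions()[3] == 1.0


def test_ns_ratio_balanced(rcrs, root_only):
    profiles = {"S1": {"11377", "10398"}}  # one syn + one nonsyn
    report, _, _ = _report(rcrs, profiles, root_only)
    x, inf = report.ns_ratio()
    assert not inf and x == pytest.approx(1.0)
    assert report.nonsynonymous_share() == pytest.approx(0.5)


def test_event_vs_variant_counting(rcrs, root_only):
    # conflicting sharing forces 11377 onto two independent edges:
    # 4 placed events but only 3 distinct variants
    profiles = {"S1": {"11377", "5029"}, "S2": {"11377", "10081"},
                "S3": {"5029"}}
    ev_report, _, _ = _report(rcrs, profiles, root_only, counting="events")
    var_report, _, _ = _report(rcrs, profiles, root_only, counting="variants")
    assert ev_report.n_substitution_events == 4
    assert var_report.n_substitution_events == 3


def test_region_filter(rcrs, root_only):
    profiles = {"S1": {"11377", "16092"}}  # one coding, one control
    full, _, _ = _report(rcrs, profiles, root_only)
    coding, _, _ = _report(rcrs, profiles, root_only, region=(577, 16023))
    assert full.n_substitution_events == 2
    assert coding.n_substitution_events == 1


def test_unannotated_event_is_a_hard_error(rcrs, root_only):
    profiles = {"S1": {"11377"}}
    calls = {"S1": call_haplogroup("S1", profiles["S1"], root_only)}
    mp = build_mp_tree(profiles, root_only, calls)
    part = partition_variants(mp)
    with pytest.raises(CoverageError):
        tabulate_spectrum(mp, {}, part)


def test_ts_tv_and_spectrum(rcrs, root_only):
    profiles = {"S1": {"3010", "11377", "12285G"}}
    report, _, _ = _report(rcrs, profiles, root_only)
    assert report.ts_tv_counts() == (2, 1)
    spec = report.tv_spectrum()
    assert spec == {"A": 0, "G": 1, "C": 0, "T": 0}


def test_all_transition_cohort_has_empty_tv_spectrum(rcrs, root_only):
    report, _, _ = _report(rcrs, {"S1": {"3010", "11377"}}, root_only)
    assert report.tv_spectrum() == {"A": 0, "G": 0, "C": 0, "T": 0}
    assert report.ts_tv_ratio() == np.inf


def test_young_old_equal_odds(rcrs, root_only):
    # S1,S2 share a syn+nonsyn pair (internal edge) and each carries a
    # private syn+nonsyn pair: odds ratio 1 -> statistic 0, p = 1
    profiles = {
        "S1": {"11377", "10398", "10205", "5029"},
        "S2": {"11377", "10398", "15175", "10081"},
    }
    report, _, _ = _report(rcrs, profiles, root_only)
    table = report.young_old_table()
    assert table.tolist() == [[2, 2], [1, 1]]
    result = report.young_old_test()
    assert result.chi2 == pytest.approx(0.0, abs=1e-12)
    assert result.p_value == pytest.approx(1.0)


def test_young_old_zero_margin_skipped(rcrs, root_only):
    report, _, _ = _report(rcrs, {"S1": {"11377", "10205"}}, root_only)
    assert report.young_old_test().skipped


def test_correlation_perfect_when_proportional(rcrs):
    """Counts exactly proportional to gene length give R^2 = 1."""
    from mtevol.spectrum import SpectrumReport
    import pandas as pd

    genes = rcrs.protein_genes()
    rows = []
    for g in genes:
        for _ in range(round(g.length / 100)):  # ~proportional counts
            rows.append(
                {"kind": "transition", "region_class": "protein",
                 "gene": g.gene, "effect": "synonymous", "codon_position": 3,
                 "status": "private", "alt": "A", "stratum": ""}
            )
    report = SpectrumReport(pd.DataFrame(rows), pd.DataFrame(), None, "events")
    c = report.gene_length_correlation(rcrs, "all")
    assert c.r2 == pytest.approx(1.0, abs=0.01)


def test_correlation_matches_direct_formula(rcrs, root_only):
    rng = np.random.default_rng(5)
    tokens = ["11377", "10205", "15175", "4796", "11026", "10398", "5029",
              "13708", "14831", "5911", "4674", "14798"]
    profiles = {f"S{i}": set(rng.choice(tokens, size=5, replace=False))
                for i in range(8)}
    report, _, _ = _report(rcrs, profiles, root_only)
    c = report.gene_length_correlation(rcrs, "all")
    counts = report.gene_counts("all")
    x = np.array([g.length for g in rcrs.protein_genes()], float)
    y = np.array([counts.get(g.gene, 0) for g in rcrs.protein_genes()], float)
    r_direct = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    assert abs(c.r - r_direct) < 1e-9


def test_stratified_reports_sum_to_total(rcrs, root_only):
    profiles = {
        "S1": {"11377", "5029"}, "S2": {"11377", "10081"}, "S3": {"10205"},
    }
    strata = {"S1": "carrier", "S2": "non-carrier", "S3": "non-carrier"}
    calls = {s: call_haplogroup(s, t, root_only) for s, t in profiles.items()}
    mp = build_mp_tree(profiles, root_only, calls)
    part = partition_variants(mp)
    anns = {
        ev.token: annotate_variant(parse_variant(ev.token, rcrs), rcrs)
        for ev in part.events
    }
    report = tabulate_spectrum(mp, anns, part, strata=strata)
    labels = set(report.events["stratum"])
    total = report.n_substitution_events
    assert sum(report.stratum(lb).n_substitution_events for lb in labels) == total
    # the shared 11377 edge spans both strata
    assert "mixed" in labels


def test_viamt_and_class_changes(rcrs, root_only):
    profiles = {"S1": {"10398", "4674", "11778"}}
    report, _, _ = _report(rcrs, profiles, root_only)
    # T->A and I->V stay within VIAMT; R->H does not
    assert report.viamt_count() == 2
    classes = report.aa_class_change_counts()
    assert classes["basic polar-basic polar"] == 1


def test_aa_hit_ratio(rcrs, root_only):
    report, _, _ = _report(rcrs, {"S1": {"10398", "4674"}}, root_only)
    # hits: T:1 A:1 (10398), I:1 V:1 (4674) -> group {T,V} mean 1,
    # others mean 2/18
    ratio = report.aa_hit_ratio(("T", "V"))
    assert ratio == pytest.approx((2 / 2) / (2 / 18))


def test_report_is_pure_function_of_inputs(rcrs, root_only):
    profiles = {"S1": {"11377", "10398"}, "S2": {"11377"}}
    r1, _, _ = _report(rcrs, profiles, root_only)
    r2, _, _ = _report(rcrs, profiles, root_only)
    assert r1.summary(rcrs) == r2.summary(rcrs)
    assert r1.events.equals(r2.events)
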