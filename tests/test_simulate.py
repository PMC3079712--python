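"""Synthetic-data generator: determinism, layout validity, rate model."""

import numpy as np
import pytest
from scipy import stats

from mtevol.haplocall import call_haplogroup
from mtevol.reference import translate_codon
from mtevol.simulate import (
    GroundTruth,
    RecoveryReport,
    SimulationConfig,
    recovery_report,
    simulate_cohort,
    simulate_reference,
)
from mtevol.variants import parse_variant


def test_reference_layout(small_config, small_ref):
    types = [a.feature_type for a in small_ref.annotations]
    assert types.count("protein") == small_config.n_protein_genes
    assert types.count("tRNA") == small_config.n_trna_genes
    assert types.count("rRNA") == small_config.n_rrna_genes
    lo, hi = small_ref.coding_range
    assert all(lo <= a.start and a.end <= hi for a in small_ref.annotations)


def test_reference_deterministic(small_config):
    a = simulate_reference(small_config)
    b = simulate_reference(small_config)
    assert a.sequence == b.sequence
    assert a.annotations == b.annotations


def test_protein_frames_are_open(small_ref):
    """Translate-and-scan oracle: no internal stops, ATG start, stop end."""
    for ann in small_ref.protein_genes():
        n = small_ref.n_codons(ann)
        assert small_ref.codon(ann, 1) == "ATG"
        assert translate_codon(small_ref.codon(ann, n)) == "*"
        for number in range(1, n):
            assert translate_codon(small_ref.codon(ann, number)) != "*"


def test_layout_overflow_rejected():
    with pytest.raises(ValueError):
        simulate_reference(SimulationConfig(genome_length=1500, control_length=1400))
    with pytest.raises(ValueError):
        simulate_reference(
            SimulationConfig(genome_length=2000, n_protein_genes=20)
        )


def test_cohort_deterministic(small_config, small_ref):
    p1, t1, g1 = simulate_cohort(small_config, small_ref)
    p2, t2, g2 = simulate_cohort(small_config, small_ref)
    assert p1 == p2
    assert g1.haplogroup == g2.haplogroup and g1.private == g2.private
    from mtevol.haplotree import format_haplotree

    assert format_haplotree(t1) == format_haplotree(t2)


def test_empty_cohort(small_config, small_ref):
    config = SimulationConfig(**{**small_config.__dict__, "n_samples": 0})
    profiles, _, truth = simulate_cohort(config, small_ref)
    assert profiles == {} and truth.haplogroup == {}


def test_noise_free_profiles_equal_their_path(small_config, small_ref):
    config = SimulationConfig(
        **{
            **small_config.__dict__,
            "private_mutation_mean": 0.0,
            "heteroplasmy_prob": 0.0,
        }
    )
    profiles, tree, truth = simulate_cohort(config, small_ref)
    for s, toks in profiles.items():
        assert set(toks) == tree.cumulative_tokens(truth.haplogroup[s])


def test_frequency_vector_must_match_tree(small_config, small_ref):
    config = SimulationConfig(
        **{**small_config.__dict__, "haplogroup_freqs": {"NOSUCH": 1.0}}
    )
    with pytest.raises(ValueError):
        simulate_cohort(config, small_ref)
    bad_sum = SimulationConfig(
        **{**small_config.__dict__, "haplogroup_freqs": {"HG1": 0.2}}
    )
    with pytest.raises(ValueError):
        simulate_cohort(bad_sum, small_ref)


def test_profiles_are_parseable_and_truth_consistent(small_config, small_ref):
    profiles, tree, truth = simulate_cohort(small_config, small_ref)
    for s, toks in profiles.items():
        for t in toks:
            parse_variant(t, small_ref)  # must not raise
        expected = (
            tree.cumulative_tokens(truth.haplogroup[s])
            | set(truth.private[s])
            | set(truth.heteroplasmies[s])
        )
        assert set(toks) == expected


def test_hotspot_sites_mutate_more_often():
    """Rank test: hotspot sites accumulate more private hits than baseline."""
    config = SimulationConfig(
        seed=23, n_samples=400, genome_length=4000, control_length=400,
        n_protein_genes=2, n_trna_genes=2, n_rrna_genes=1, rrna_length=300,
        tree_depth=1, branching_factor=2, n_hotspots=5,
        hotspot_multiplier=50.0, private_mutation_mean=2.0,
        nonsyn_keep_prob=1.0,
    )
    ref = simulate_reference(config)
    profiles, _, truth = simulate_cohort(config, ref)
    counts = {}
    for s, privates in truth.private.items():
        for t in privates:
            pos = int(t.rstrip("ACGT"))
            counts[pos] = counts.get(pos, 0) + 1
    hot = [counts.get(p, 0) for p in truth.hotspot_positions]
    rng = np.random.default_rng(1)
    baseline_sites = rng.choice(
        [p for p in range(1, ref.length + 1) if p not in truth.hotspot_positions],
        size=200, replace=False,
    )
    cold = [counts.get(int(p), 0) for p in baseline_sites]
    u = stats.mannwhitneyu(hot, cold, alternative="greater")
    assert u.pvalue < 1e-4


def test_ts_tv_bias_matches_configuration():
    config = SimulationConfig(
        seed=31, n_samples=300, private_mutation_mean=4.0,
        nonsyn_keep_prob=1.0, heteroplasmy_prob=0.0, n_hotspots=0,
        genome_length=8000, control_length=600,
    )
    ref = simulate_reference(config)
    _, _, truth = simulate_cohort(config, ref)
    tokens = [t for toks in truth.private.values() for t in toks]
    tv = sum(t[-1].isalpha() for t in tokens)
    ts = len(tokens) - tv
    p_expected = config.ts_tv_ratio / (config.ts_tv_ratio + 1)
    ci = stats.binomtest(ts, ts + tv, p_expected).proportion_ci(0.999)
    assert ci.low <= p_expected <= ci.high


def test_replacement_filter_creates_position2_deficit():
    """With selection on, second codon positions are depleted relative to
    the neutral generator (they are the most replacement-prone)."""
    base = dict(
        seed=5, n_samples=300, private_mutation_mean=4.0, n_hotspots=0,
        heteroplasmy_prob=0.0, genome_length=8000, control_length=600,
        n_trna_genes=2, n_rrna_genes=1,
    )
    ref = simulate_reference(SimulationConfig(**base, nonsyn_keep_prob=1.0))

    def fraction_pos2(keep):
        config = SimulationConfig(**base, nonsyn_keep_prob=keep)
        _, _, truth = simulate_cohort(config, ref)
        from mtevol.annotate import annotate_variant

        positions = []
        for toks in truth.private.values():
            for t in toks:
                c = annotate_variant(parse_variant(t, ref), ref).primary
                if c.codon_position is not None:
                    positions.append(c.codon_position)
        return positions.count(2) / len(positions)

    assert fraction_pos2(0.3) < fraction_pos2(1.0) - 0.05


def test_recovery_report_perfect_and_chance(small_config, small_ref):
    profiles, tree, truth = simulate_cohort(small_config, small_ref)
    calls = {s: truth.haplogroup[s] for s in profiles}
    extras = {s: set(truth.private[s]) for s in profiles}
    rep = recovery_report(
        calls, extras, set(truth.recurrent_positions), set(), truth,
        small_ref.length,
    )
    assert rep.haplogroup_accuracy == 1.0
    assert rep.private_precision == 1.0 and rep.private_recall == 1.0
    assert rep.recurrent_sensitivity == 1.0

    # shuffled truth labels give roughly chance-level accuracy
    shuffled = dict(zip(sorted(calls), [calls[s] for s in sorted(calls, reverse=True)]))
    rep2 = recovery_report(
        shuffled, extras, set(), set(), truth, small_ref.length
    )
    assert rep2.haplogroup_accuracy < 1.0


def test_recovery_report_id_mismatch(small_config, small_ref):
    _, _, truth = simulate_cohort(small_config, small_ref)
    with pytest.raises(ValueError):
        recovery_report({"X": "HG1"}, {}, set(), set(), truth, small_ref.length)


def test_ground_truth_round_trip(tmp_path, small_config, small_ref):
    _, _, truth = simulate_cohort(small_config, small_ref)
    truth.to_json(tmp_path / "t.json")
    again = GroundTruth.from_json(tmp_path / "t.json")
    assert again.haplogroup == truth.haplogroup
    assert again.recurrent_positions == truth.recurrent_positions
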