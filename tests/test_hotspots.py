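import numpy as np
import pandas as pd
import pytest

import cki
from cki.hotspots import (
    analyze_hotspots,
    detect_clusters,
    gene_clustering_score,
    hotspot_significance,
    positional_counts,
)
from helpers import make_mutations


class TestPositionalCounts:
    def test_recurrent_residue(self):
        mt = make_mutations([("A", 600, "missense", f"T{i}") for i in range(5)])
        assert positional_counts(mt, "A", 766) == {600: 5}

    def test_silent_and_other_excluded(self):
        mt = make_mutations([("A", 10, "silent", "T1"), ("A", 11, "other", "T2"),
                             ("A", 12, "nonsense", "T3")])
        assert positional_counts(mt, "A", 100) == {12: 1}

    def test_empty_table(self):
        assert positional_counts(make_mutations([]), "A", 100) == {}

    def test_same_sample_same_residue_counts_once(self):
        mt = make_mutations([("A", 7, "insertion", "T1"), ("A", 7, "insertion", "T1"),
                             ("A", 7, "missense", "T2")])
        assert positional_counts(mt, "A", 50) == {7: 2}

    def test_position_beyond_length_dropped_with_warning(self, caplog):
        mt = make_mutations([("A", 900, "missense", "T1"), ("A", 5, "missense", "T2")])
        with caplog.at_level("WARNING"):
            hist = positional_counts(mt, "A", 100)
        assert hist == {5: 1}
        assert "beyond protein length" in caplog.text


class TestDetectClusters:
    def test_uniform_spread_has_no_seeds(self):
        hist = {r: 1 for r in range(1, 11)}
        assert detect_clusters(hist, 500, 10) == []

    def test_single_residue_concentration(self):
        assert detect_clusters({300: 10}, 500, 10) == [(300, 300, 10)]

    def test_nearby_seeds_merge(self):
        hist = {100: 6, 103: 6}
        clusters = detect_clusters(hist, 500, 12, max_gap=5)
        assert clusters == [(100, 103, 12)]

    def test_distant_seeds_stay_separate(self):
        hist = {100: 6, 200: 6}
        clusters = detect_clusters(hist, 500, 12, max_gap=5)
        assert clusters == [(100, 100, 6), (200, 200, 6)]

    def test_extension_through_adjacent_mutated_residues(self):
        # residue 101 has 2 mutations > background 20/500, joins the cluster
        hist = {100: 16, 101: 2, 110: 1, 200: 1}
        clusters = detect_clusters(hist, 500, 20)
        assert clusters == [(100, 101, 18)]


class TestClusteringScore:
    def test_bounds_and_arithmetic(self):
        assert gene_clustering_score([(1, 1, 10)], 10) == 1.0
        assert gene_clustering_score([], 10) == 0.0
        assert gene_clustering_score([(1, 1, 5), (9, 9, 2)], 10) == pytest.approx(0.7)

    def test_invariant_to_record_order_and_barcodes(self):
        rows = [("A", 50, "missense", f"T{i}") for i in range(8)]
        rows += [("A", r, "missense", f"U{r}") for r in (1, 99, 150, 200)]
        mt1 = make_mutations(rows)
        mt2 = make_mutations(rows[::-1])
        h1 = positional_counts(mt1, "A", 300)
        h2 = positional_counts(mt2, "A", 300)
        assert h1 == h2
        c1 = detect_clusters(h1, 300, sum(h1.values()))
        assert gene_clustering_score(c1, 12) == gene_clustering_score(
            detect_clusters(h2, 300, sum(h2.values())), 12)


class TestSignificance:
    def test_identical_scores_are_unremarkable(self):
        stats = {f"G{i}": (0.3, 10, [(1, 1, 3)]) for i in range(25)}
        res = hotspot_significance(stats)
        for r in res.values():
            assert r.z == pytest.approx(0.0)
            assert r.p_value == pytest.approx(0.5)
            assert not r.hotspot_flag

    def test_minimum_mutation_count_gate(self):
        stats = {f"G{i}": (0.0, 10, []) for i in range(30)}
        stats["HOT4"] = (0.9, 4, [(5, 5, 4)])  # extreme but only 4 mutations
        stats["HOT9"] = (0.9, 9, [(5, 5, 8)])
        res = hotspot_significance(stats)
        assert res["HOT4"].p_value < 0.05 and not res["HOT4"].hotspot_flag
        assert res["HOT9"].hotspot_flag

    def test_background_too_small_is_an_error(self):
        stats = {f"G{i}": (0.2, 6, []) for i in range(10)}
        with pytest.raises(ValueError, match="background"):
            hotspot_significance(stats)

    def test_planted_hotspots_recovered_in_simulation(self):
        cfg = cki.SimulationConfig(n_genes=100, n_tumor=200, n_normal=10,
                                   frac_hotspot=0.2, gene_mut_rate=20,
                                   hotspot_concentration=0.6, seed=5)
        bundle, manifest = cki.simulate_cohort(cfg)
        lengths = {g: bundle.annotations.protein_length(g)
                   for g in bundle.expression.gene_ids}
        res = analyze_hotspots(bundle.mutations, lengths)
        planted = manifest.planted("planted_hotspot")
        assert np.mean([res[g].hotspot_flag for g in planted]) >= 0.9
        nulls = [g for g in res if g not in set(planted)]
        assert np.mean([res[g].hotspot_flag for g in nulls]) <= 0.05


def _permutation_flags(bundle, lengths, rng, n_perm=2000, alpha=0.05,
                       min_mutations=5):
    """Independent oracle: per-gene permutation test that re-places each
    gene's mutations uniformly over its protein and compares clustering
    scores."""
    from cki.hotspots import QUALIFYING_CLASSES

    flags = {}
    rec = bundle.mutations.records
    for gene in bundle.expression.gene_ids:
        length = lengths[gene]
        sub = rec[(rec["gene"] == gene)
                  & rec["variant_class"].isin(QUALIFYING_CLASSES)]
        n = len(sub)
        if n == 0:
            flags[gene] = False
            continue
        hist = positional_counts(bundle.mutations, gene, length)
        total = sum(hist.values())
        obs = gene_clustering_score(detect_clusters(hist, length, total), total)
        exceed = 0
        for _ in range(n_perm):
            pos = rng.integers(1, length + 1, size=total)
            h = {}
            for p in pos:
                h[p] = h.get(p, 0) + 1
            s = gene_clustering_score(detect_clusters(h, length, total), total)
            if s >= obs:
                exceed += 1
        p_perm = (exceed + 1) / (n_perm + 1)
        flags[gene] = bool(p_perm < alpha and total >= min_mutations)
    return flags


def test_flags_agree_with_permutation_oracle():
    cfg = cki.SimulationConfig(n_genes=50, n_tumor=100, n_normal=10,
                               frac_hotspot=0.2, gene_mut_rate=15,
                               hotspot_concentration=0.6, seed=21)
    bundle, _ = cki.simulate_cohort(cfg)
    lengths = {g: bundle.annotations.protein_length(g)
               for g in bundle.expression.gene_ids}
    res = analyze_hotspots(bundle.mutations, lengths)
    oracle = _permutation_flags(bundle, lengths, np.random.default_rng(0))
    agree = np.mean([res[g].hotspot_flag == oracle[g] for g in oracle])
    assert agree >= 0.9
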