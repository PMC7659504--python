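import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cki.scoring import (
    GeneScoreCard,
    assemble_scorecard,
    cross_cohort_spearman,
    rank_cohort,
    score_table,
    summarize_by_annotation,
    top_quartile_overlap,
)


def _card(gene, cki_percent, **kwargs):
    c = GeneScoreCard(gene=gene, cohort="X", dge_component=0,
                      survival_component=0, hotspot_component=0,
                      clinical_components={}, cki_percent=cki_percent,
                      max_score=3)
    for k, v in kwargs.items():
        setattr(c, k, v)
    return c


class TestAssemble:
    def test_all_zero_gives_zero(self):
        c = assemble_scorecard("A", "X", 0, 0, 0, {"T": 0.0, "N": 0.0})
        assert c.raw_score == 0.0 and c.cki_percent == 0.0

    def test_all_maximal_gives_one_hundred(self):
        c = assemble_scorecard("A", "X", 1, 1, 1, {"T": 1.0, "N": 1.0, "M": 1.0})
        assert c.raw_score == 6.0 and c.max_score == 6
        assert c.cki_percent == 100.0

    def test_partial_credit_arithmetic(self):
        # raw 4.25 over max 6 is the largest ratio the scoring admits with
        # three binary hits plus fractional clinical credit of 1.25
        c = assemble_scorecard("A", "X", 1, 1, 1, {"T": 1.0, "N": 0.25, "M": 0.0})
        assert c.raw_score == pytest.approx(4.25)
        assert round(c.cki_percent, 2) == 70.83

    def test_unavailable_component_shrinks_the_maximum(self):
        c = assemble_scorecard("A", "X", None, 1, 0, {"T": 0.5})
        assert c.max_score == 3  # survival + hotspot + T
        assert c.cki_percent == pytest.approx(100 * 1.5 / 3)

    def test_no_clinical_data_keeps_the_three_binaries(self):
        c = assemble_scorecard("A", "X", 1, 0, 0, {})
        assert c.max_score == 3

    def test_invalid_components_rejected(self):
        with pytest.raises(ValueError):
            assemble_scorecard("A", "X", 2, 0, 0, {})
        with pytest.raises(ValueError):
            assemble_scorecard("A", "X", 0, 0, 0, {"T": 1.5})
        with pytest.raises(ValueError):
            assemble_scorecard("A", "X", None, None, None, {})

    @given(
        st.tuples(st.integers(0, 1), st.integers(0, 1), st.integers(0, 1)),
        st.lists(st.floats(0, 1, allow_nan=False), min_size=0, max_size=6),
        st.integers(0, 8),
    )
    @settings(derandomize=True, max_examples=200)
    def test_monotone_in_every_component(self, binaries, clinical, bump_idx):
        params = {f"p{i}": v for i, v in enumerate(clinical)}
        base = assemble_scorecard("A", "X", *binaries, params)
        assert 0.0 <= base.cki_percent <= 100.0
        assert base.raw_score <= base.max_score
        # bump one component upward; the CKI must not decrease
        d, s, h = binaries
        if bump_idx < 3:
            bumped = [d, s, h]
            bumped[bump_idx] = 1
            higher = assemble_scorecard("A", "X", *bumped, params)
        elif params:
            key = list(params)[bump_idx % len(params)]
            params2 = dict(params)
            params2[key] = min(1.0, params2[key] + 0.5)
            higher = assemble_scorecard("A", "X", d, s, h, params2)
        else:
            return
        assert higher.cki_percent >= base.cki_percent - 1e-9


class TestRanking:
    def test_competition_ranking_with_ties(self):
        cards = [_card(g, s) for g, s in
                 zip("ABCD", [90.0, 70.0, 70.0, 10.0])]
        ranked = rank_cohort(cards)
        assert [(c.gene, c.rank) for c in ranked] == [
            ("A", 1), ("B", 2), ("C", 2), ("D", 4)]

    def test_all_equal_all_rank_one(self):
        ranked = rank_cohort([_card(g, 50.0) for g in "ABC"])
        assert all(c.rank == 1 for c in ranked)
        assert [c.gene for c in ranked] == ["A", "B", "C"]

    def test_distinct_scores_are_a_permutation(self):
        rng = np.random.default_rng(3)
        scores = rng.permutation(20) * 5.0
        ranked = rank_cohort([_card(f"G{i}", s) for i, s in enumerate(scores)])
        assert sorted(c.rank for c in ranked) == list(range(1, 21))

    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValueError):
            rank_cohort([_card("A", 1.0), _card("A", 2.0)])


class TestCrossCohort:
    def test_self_correlation_is_one_and_reversal_minus_one(self):
        genes = [f"G{i}" for i in range(10)]
        up = pd.Series(np.arange(10.0), index=genes)
        table = pd.DataFrame({"A": up, "B": up[::-1].values, "C": up * 2})
        corr = cross_cohort_spearman(table)
        assert corr.loc["A", "A"] == 1.0
        assert corr.loc["A", "B"] == pytest.approx(-1.0)
        assert corr.loc["A", "C"] == pytest.approx(1.0)

    def test_insufficient_overlap_is_missing(self):
        table = pd.DataFrame({"A": [1.0, 2.0, np.nan, np.nan],
                              "B": [np.nan, np.nan, 1.0, 2.0]},
                             index=list("wxyz"))
        corr = cross_cohort_spearman(table)
        assert np.isnan(corr.loc["A", "B"])

    def test_cohorts_sharing_planted_genes_correlate(self, patient_expression):
        import cki

        base = dict(n_genes=80, n_tumor=120, n_normal=40, composite_fraction=0.2,
                    planting_seed=77)
        ca, _ = cki.score_cohort(cki.simulate_cohort(
            cki.SimulationConfig(cohort="A", seed=101, **base))[0])
        cb, _ = cki.score_cohort(cki.simulate_cohort(
            cki.SimulationConfig(cohort="B", seed=102, **base))[0])
        corr = cross_cohort_spearman(score_table({"A": ca, "B": cb}))
        assert corr.loc["A", "B"] > 0


class TestTopQuartile:
    def test_identical_cohorts_jaccard_one(self):
        cards = [_card(f"G{i}", float(i)) for i in range(20)]
        shared, jac = top_quartile_overlap(cards, cards)
        assert shared == 5 and jac == 1.0

    def test_disjoint_top_sets(self):
        a = [_card(f"G{i}", 100.0 if i < 5 else 0.0) for i in range(20)]
        b = [_card(f"G{i}", 100.0 if i >= 15 else 0.0) for i in range(20)]
        shared, jac = top_quartile_overlap(a, b)
        assert shared == 0 and jac == 0.0

    def test_five_swaps_leave_twenty_shared(self):
        # 100 genes; B's top 25 replaces 5 of A's top genes with outsiders
        scores_a = {f"G{i:03d}": 100.0 - i for i in range(100)}
        scores_b = dict(scores_a)
        for i in range(5):  # demote 5 top genes, promote 5 others
            scores_b[f"G{i:03d}"] = 0.5
            scores_b[f"G{i + 50:03d}"] = 99.0
        a = [_card(g, s) for g, s in scores_a.items()]
        b = [_card(g, s) for g, s in scores_b.items()]
        shared, _ = top_quartile_overlap(a, b)
        assert shared == 20


class TestAnnotationSummary:
    def test_single_stratum_reports_descriptives_only(self):
        cards = [_card(f"G{i}", float(i), tdl="Tbio") for i in range(5)]
        rep = summarize_by_annotation(cards, "tdl")
        assert rep["kruskal_p"] is None
        assert rep["groups"]["Tbio"]["n"] == 5

    def test_identical_strata_are_indistinguishable(self):
        cards = [_card(f"A{i}", float(i), tdl="Tclin") for i in range(5)]
        cards += [_card(f"B{i}", float(i), tdl="Tdark") for i in range(5)]
        rep = summarize_by_annotation(cards, "tdl")
        assert rep["kruskal_p"] == pytest.approx(1.0)

    def test_planted_moa_targets_score_higher(self, recovery_scored):
        cards, _ = recovery_scored
        rep = summarize_by_annotation(cards, "moa")
        assert rep["groups"]["MOA"]["mean"] > rep["groups"]["non-MOA"]["mean"]
        assert rep["kruskal_p"] < 0.05
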