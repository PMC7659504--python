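import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cki
from cki.clinical import (
    PARAMETERS,
    available_parameters,
    clinical_score,
    clinical_scores_matrix,
    collapse_substages,
    pairwise_stage_score,
    stage_anova,
    stage_assignments,
)
from helpers import make_clinical


class TestCollapseSubstages:
    @pytest.mark.parametrize(
        "raw,param,expected",
        [
            ("t1a", "T", 1), ("t1b1", "T", 1), ("T2C", "T", 2), ("t4e", "T", 4),
            ("n3a", "N", 3), ("n0", "N", 0), ("n1mi", "N", 1),
            ("m0", "M", 0), ("m1", "M", 1),
            ("g3", "grade", 3), ("G1", "grade", 1),
            ("Stage IIB", "pathologic_stage", 2), ("stage iv", "clinical_stage", 4),
            ("iii", "pathologic_stage", 3),
            ("TX", "T", None), ("nx", "N", None), ("mx", "M", None),
            ("t5", "T", None), ("", "T", None), (None, "T", None),
            ("stage x", "pathologic_stage", None),
        ],
    )
    def test_prefix_mapping(self, raw, param, expected):
        assert collapse_substages(raw, param) == expected

    @given(st.text(max_size=8))
    @settings(derandomize=True, max_examples=200)
    def test_total_and_in_range(self, raw):
        for param, (_, rng) in PARAMETERS.items():
            level = collapse_substages(raw, param)
            assert level is None or level in rng

    def test_canonical_labels_map_to_themselves(self):
        for l in range(1, 5):
            assert collapse_substages(f"t{l}", "T") == l


class TestStageAnova:
    def test_closed_form_two_groups(self):
        f, p = stage_anova([1, 2, 3, 4, 5, 6], [1, 1, 1, 2, 2, 2])
        assert f == pytest.approx(13.5, abs=1e-9)

    def test_equal_means_give_zero_f(self):
        f, p = stage_anova([1, 3, 2, 2], [1, 1, 2, 2])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_brute_force_sum_of_squares(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            sizes = rng.integers(2, 6, size=3)
            levels = np.repeat([1, 2, 3], sizes)
            x = rng.normal(size=levels.size)
            f, _ = stage_anova(x, levels)
            grand = x.mean()
            ss_between = sum(
                len(x[levels == l]) * (x[levels == l].mean() - grand) ** 2
                for l in (1, 2, 3))
            ss_within = sum(
                ((x[levels == l] - x[levels == l].mean()) ** 2).sum()
                for l in (1, 2, 3))
            f_ref = (ss_between / 2) / (ss_within / (levels.size - 3))
            assert f == pytest.approx(f_ref, rel=1e-9)

    def test_single_usable_level_is_unavailable(self):
        with pytest.raises(ValueError):
            stage_anova([1, 2, 3], [1, 1, 1])


class TestPairwiseScore:
    def test_no_difference_scores_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        levels = np.repeat([1, 2, 3, 4], 10)
        assert pairwise_stage_score(x, levels) == 0.0

    def test_all_pairs_increasing_scores_one(self):
        x = np.concatenate([np.zeros(5), np.full(5, 10.0), np.full(5, 20.0)])
        x += np.tile([0.0, 0.1, -0.1, 0.05, -0.05], 3)
        levels = np.repeat([1, 2, 3], 5)
        assert pairwise_stage_score(x, levels) == 1.0

    def test_significant_decrease_scores_zero(self):
        x = np.concatenate([np.full(5, 20.0), np.full(5, 10.0), np.zeros(5)])
        x += np.tile([0.0, 0.1, -0.1, 0.05, -0.05], 3)
        levels = np.repeat([1, 2, 3], 5)
        assert pairwise_stage_score(x, levels) == 0.0

    def test_partial_significance_is_fractional(self):
        # level 3 clearly above 1 and 2; levels 1 and 2 indistinguishable
        x = np.concatenate([np.zeros(6), np.zeros(6), np.full(6, 10.0)])
        x += np.tile([0.0, 0.1, -0.1, 0.05, -0.05, 0.02], 3)
        levels = np.repeat([1, 2, 3], 6)
        assert pairwise_stage_score(x, levels) == pytest.approx(2 / 3)
        assert pairwise_stage_score(x, levels, rule="any") == 1.0

    def test_consecutive_pairs_option(self):
        x = np.concatenate([np.zeros(6), np.zeros(6), np.full(6, 10.0)])
        x += np.tile([0.0, 0.1, -0.1, 0.05, -0.05, 0.02], 3)
        levels = np.repeat([1, 2, 3], 6)
        # consecutive tests only (1,2) and (2,3): one of two counts
        assert pairwise_stage_score(x, levels, pairs="consecutive") == pytest.approx(0.5)

    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=8, max_size=24))
    @settings(derandomize=True, max_examples=100)
    def test_score_always_in_unit_interval(self, values):
        levels = np.tile([1, 2], len(values) // 2 + 1)[: len(values)]
        try:
            score = pairwise_stage_score(np.array(values), levels)
        except ValueError:
            return
        assert 0.0 <= score <= 1.0


class TestClinicalScore:
    def test_totals_and_availability(self):
        rows = []
        # 12 patients: T separates perfectly, M has a single level (unusable)
        for i in range(12):
            rows.append({"patient_id": f"P{i:02d}",
                         "t_stage": "t1" if i < 6 else "t3",
                         "m_stage": "m0"})
        ct = make_clinical(rows)
        assign = stage_assignments(ct)
        expr = pd.Series(
            np.r_[np.zeros(6), np.full(6, 5.0)] + np.tile([0, .1, -.1, .05, -.05, .02], 2),
            index=[f"P{i:02d}" for i in range(12)])
        cs = clinical_score(expr, assign)
        assert cs.per_parameter == {"T": 1.0}
        assert cs.clinical_total == 1.0
        assert cs.parameters_available == 1
        assert available_parameters(assign) == ["T"]

    def test_no_clinical_data_scores_nothing(self):
        ct = make_clinical([{"patient_id": "P00"}, {"patient_id": "P01"}])
        assign = stage_assignments(ct)
        expr = pd.Series([1.0, 2.0], index=["P00", "P01"])
        cs = clinical_score(expr, assign)
        assert cs.clinical_total == 0.0 and cs.parameters_available == 0

    def test_planted_stage_trend_recovered(self, patient_expression):
        cfg = cki.SimulationConfig(n_genes=80, n_tumor=160, n_normal=10,
                                   frac_clinical=0.25, stage_shift=0.5, seed=13)
        bundle, manifest = cki.simulate_cohort(cfg)
        expr = patient_expression(bundle)
        assign = stage_assignments(bundle.clinical)
        mat = clinical_scores_matrix(expr, assign)
        planted = manifest.planted("planted_clinical")
        assert (mat.loc[planted, "T"] > 0).mean() >= 0.8

    def test_matrix_path_equals_per_gene_path(self, recovery_sim, patient_expression):
        bundle, _ = recovery_sim
        expr = patient_expression(bundle)
        assign = stage_assignments(bundle.clinical)
        mat = clinical_scores_matrix(expr, assign)
        for gene in list(expr.index)[::10]:
            ref = clinical_score(expr.loc[gene], assign)
            assert ref.per_parameter == {p: mat.at[gene, p] for p in mat.columns}
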