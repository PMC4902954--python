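"""Accuracy algebra, reclassification and confusion-count tests."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from earlycea import CANDIDATE_TESTS
from earlycea.strategy import (
    RA2010_CRITERIA,
    ClassificationCounts,
    DiagnosticTest,
    RiskGroup,
    StrategyMode,
    StrategySpec,
    TestAccuracy,
    classify_cohort,
    combine_add_on_all,
    combine_add_on_intermediate,
    reclassify_group,
    replacement_accuracy,
    round_half_up,
    sample_classification_counts,
)

probs = st.floats(0.0, 1.0, allow_nan=False)
accuracies = st.builds(TestAccuracy, sensitivity=probs, specificity=probs)


class TestCombineAddOnAll:
    @pytest.mark.parametrize(
        "new, expected",
        [
            ((0.60, 0.90), (0.85, 0.69)),  # B-cell gene expression
            ((0.70, 0.53), (0.89, 0.41)),  # IL-6 serum level
            ((0.90, 0.60), (0.96, 0.46)),  # MRI hands and feet
            ((0.40, 0.85), (0.77, None)),  # genetic assay; combined Sp anomaly
        ],
    )
    def test_published_combined_accuracies(self, new, expected):
        acc = combine_add_on_all(RA2010_CRITERIA, TestAccuracy(*new))
        assert round(acc.sensitivity, 2) == expected[0]
        if expected[1] is not None:
            assert round(acc.specificity, 2) == expected[1]

    def test_unrounded_values(self):
        acc = combine_add_on_all(RA2010_CRITERIA, TestAccuracy(0.60, 0.90))
        assert acc.sensitivity == pytest.approx(0.848)
        assert acc.specificity == pytest.approx(0.693)

    def test_perfect_test_saturates_sensitivity(self):
        acc = combine_add_on_all(RA2010_CRITERIA, TestAccuracy(1.0, 1.0))
        assert acc.sensitivity == 1.0
        assert acc.specificity == RA2010_CRITERIA.specificity

    @given(base=accuracies, new=accuracies)
    @settings(max_examples=200, deadline=None)
    def test_add_on_never_worse_on_se_never_better_on_sp(self, base, new):
        acc = combine_add_on_all(base, new)
        assert acc.sensitivity >= base.sensitivity - 1e-12
        assert acc.specificity <= base.specificity + 1e-12


class TestCombineAddOnIntermediate:
    SHARES = (97 / 299, 166 / 253)

    @pytest.mark.parametrize(
        "new, expected",
        [
            ((0.90, 0.60), (0.91, 0.51)),  # MRI
            ((0.40, 0.85), (0.75, 0.67)),  # genetic assay
            ((0.70, 0.53), (0.85, 0.46)),  # IL-6
            ((0.60, 0.90), (0.81, None)),  # B-cell; published Sp anomaly
        ],
    )
    def test_published_combined_accuracies(self, new, expected):
        acc = combine_add_on_intermediate(
            RA2010_CRITERIA, TestAccuracy(*new), *self.SHARES
        )
        assert round(acc.sensitivity, 2) == expected[0]
        if expected[1] is not None:
            assert round(acc.specificity, 2) == expected[1]

    def test_zero_shares_leave_base_unchanged(self):
        acc = combine_add_on_intermediate(
            RA2010_CRITERIA, TestAccuracy(0.9, 0.6), 0.0, 0.0
        )
        assert acc == RA2010_CRITERIA

    def test_share_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            combine_add_on_intermediate(
                RA2010_CRITERIA, TestAccuracy(0.9, 0.6), 1.5, 0.5
            )

    @given(base=accuracies, new=accuracies)
    @settings(max_examples=200, deadline=None)
    def test_all_negatives_in_intermediate_recovers_add_on_all(self, base, new):
        """With shares (1-se_b, sp_b) every criteria-negative patient is
        retested, so the stratum-weighted formula equals the serial one."""
        acc = combine_add_on_intermediate(
            base, new, 1.0 - base.sensitivity, base.specificity
        )
        full = combine_add_on_all(base, new)
        assert acc.sensitivity == pytest.approx(full.sensitivity, abs=1e-12)
        assert acc.specificity == pytest.approx(full.specificity, abs=1e-12)

    @given(new=accuracies, fn_share=probs, tn_share=probs)
    @settings(max_examples=200, deadline=None)
    def test_never_below_base_sensitivity_never_above_base_specificity(
        self, new, fn_share, tn_share
    ):
        acc = combine_add_on_intermediate(RA2010_CRITERIA, new, fn_share, tn_share)
        assert acc.sensitivity >= RA2010_CRITERIA.sensitivity - 1e-12
        assert acc.specificity <= RA2010_CRITERIA.specificity + 1e-12


class TestReplacement:
    @pytest.mark.parametrize("se, sp", [(0.60, 0.90), (1.0, 1.0), (0.40, 0.85)])
    def test_identity(self, se, sp):
        assert replacement_accuracy(TestAccuracy(se, sp)) == TestAccuracy(se, sp)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            TestAccuracy(1.2, 0.5)


class TestReclassification:
    INTERMEDIATE = RiskGroup("intermediate", 97, 166)
    LOW = RiskGroup("low", 17, 29)

    @pytest.mark.parametrize(
        "test_name, expected_int, expected_low",
        [
            ("b_cell", (75, 188), (13, 33)),
            ("il6", (146, 117), (26, 20)),
            ("mri", (154, 109), (26, 20)),
            ("genetic", (64, 199), (11, 35)),
        ],
    )
    def test_published_counts(self, test_name, expected_int, expected_low):
        acc = CANDIDATE_TESTS[test_name].accuracy
        to_high, to_low = reclassify_group(self.INTERMEDIATE, acc)
        assert (to_high, to_low) == expected_int
        to_high, to_low = reclassify_group(self.LOW, acc)
        # low-risk rows agree within one patient of the published cells
        assert abs(to_high - expected_low[0]) <= 1
        assert abs(to_low - expected_low[1]) <= 1
        assert to_high + to_low == self.LOW.size

    def test_perfect_test_sends_all_ra_high(self):
        to_high, to_low = reclassify_group(self.INTERMEDIATE, TestAccuracy(1.0, 1.0))
        assert to_high == self.INTERMEDIATE.n_ra
        assert to_low == self.INTERMEDIATE.n_non_ra


class TestClassifyCohort:
    def test_current_strategy_reproduces_published_row(self, cohort, current_strategy):
        counts = classify_cohort(cohort, current_strategy)
        assert counts == ClassificationCounts(tp=185, fp=58, tn=195, fn=114)

    def test_add_on_all_bcell_near_published(self, cohort, bcell_add_on_all):
        counts = classify_cohort(cohort, bcell_add_on_all)
        assert abs(counts.tp - 254) <= 1
        assert abs(counts.fn - 46) <= 1

    def test_perfect_replacement_has_no_false_negatives(self, cohort):
        perfect = DiagnosticTest("perfect", TestAccuracy(1.0, 1.0), 0.0)
        counts = classify_cohort(
            cohort, StrategySpec(StrategyMode.REPLACEMENT, perfect)
        )
        assert counts.tp == cohort.total_ra
        assert counts.fn == 0
        assert counts.fp == 0

    @pytest.mark.parametrize("test_name", list(CANDIDATE_TESTS))
    @pytest.mark.parametrize(
        "mode",
        [StrategyMode.ADD_ON_ALL, StrategyMode.ADD_ON_INTERMEDIATE, StrategyMode.REPLACEMENT],
    )
    def test_counts_sum_to_cohort_total(self, cohort, test_name, mode):
        spec = StrategySpec(mode, CANDIDATE_TESTS[test_name])
        assert classify_cohort(cohort, spec).total == cohort.total_n

    def test_bernoulli_mode_conserves_totals_and_centres_on_expectation(self, cohort):
        import numpy as np

        spec = StrategySpec(StrategyMode.ADD_ON_ALL, CANDIDATE_TESTS["b_cell"])
        expected = classify_cohort(cohort, spec)
        rng = np.random.default_rng(7)
        draws = [sample_classification_counts(cohort, spec, rng) for _ in range(300)]
        assert all(d.total == cohort.total_n for d in draws)
        mean_tp = sum(d.tp for d in draws) / len(draws)
        # binomial SE of TP is ~sqrt(114*p(1-p)) < 3.3; 3 SE over 300 draws
        assert abs(mean_tp - expected.tp) < 3 * 3.3 / (300**0.5) + 0.5


class TestValidation:
    def test_current_strategy_rejects_test(self):
        with pytest.raises(ValueError):
            StrategySpec(StrategyMode.CURRENT, CANDIDATE_TESTS["b_cell"])

    def test_new_mode_requires_test(self):
        with pytest.raises(ValueError):
            StrategySpec(StrategyMode.ADD_ON_ALL)

    def test_negative_unit_cost_rejected(self):
        with pytest.raises(ValueError):
            DiagnosticTest("bad", TestAccuracy(0.5, 0.5), -1.0)

    @pytest.mark.parametrize("x, expected", [(74.8, 75), (63.5, 64), (0.49, 0), (2.5, 3)])
    def test_round_half_up(self, x, expected):
        assert round_half_up(x) == expected
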