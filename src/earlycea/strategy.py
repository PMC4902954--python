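"""Algebra of diagnostic test strategies for suspected rheumatoid arthritis.

A cohort of patients with inflammatory arthritis is worked up with the
ACR/EULAR 2010 classification criteria ("RA-2010 criteria"), which stratify
patients into high risk (criteria-positive, >=6 of 10 points), intermediate
risk (3-5 points) and low risk.  A candidate diagnostic test (B-cell gene
expression, IL-6 serum level, MRI of hands and feet, genetic assay, ...) can
be positioned three ways relative to the criteria:

* ``add_on_all`` - every patient also receives the new test; a positive on
  either classifies the patient as RA (believe-the-positive serial
  combination).
* ``add_on_intermediate`` - only the intermediate-risk stratum is retested.
* ``replacement`` - the new test replaces the blood tests and radiographs of
  the criteria altogether.

This module is pure accuracy/count algebra: it combines sensitivities and
specificities, reclassifies risk groups and produces expected confusion
(TP/FP/TN/FN) counts at 12 months.  Everything downstream (costs, QALYs,
microsimulation) consumes its outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Tuple

__all__ = [
    "TestAccuracy",
    "DiagnosticTest",
    "StrategyMode",
    "StrategySpec",
    "RiskGroup",
    "RiskStratifiedCohort",
    "ClassificationCounts",
    "RA2010_CRITERIA",
    "round_half_up",
    "combine_add_on_all",
    "combine_add_on_intermediate",
    "replacement_accuracy",
    "resolve_strategy_accuracy",
    "reclassify_group",
    "classify_cohort",
    "sample_classification_counts",
    "newly_detected_fraction",
    "tested_fraction",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves going up (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


def _check_prob(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class TestAccuracy:
    """Sensitivity/specificity pair of a test or combined strategy."""

    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        _check_prob(self.sensitivity, "sensitivity")
        _check_prob(self.specificity, "specificity")


@dataclass(frozen=True)
class DiagnosticTest:
    """A named candidate test with a bundled per-patient unit cost (EUR).

    The unit cost covers everything administered per tested patient, e.g.
    four MRI scans (both hands and both feet) count as one unit cost.
    """

    name: str
    accuracy: TestAccuracy
    unit_cost: float

    def __post_init__(self) -> None:
        if self.unit_cost < 0:
            raise ValueError(f"unit_cost must be >= 0, got {self.unit_cost!r}")


class StrategyMode(str, Enum):
    CURRENT = "current"
    ADD_ON_ALL = "add_on_all"
    ADD_ON_INTERMEDIATE = "add_on_intermediate"
    REPLACEMENT = "replacement"


@dataclass(frozen=True)
class StrategySpec:
    """A diagnostic strategy: the current criteria alone, or a positioning
    of a new test relative to them."""

    mode: StrategyMode
    test: Optional[DiagnosticTest] = None

    def __post_init__(self) -> None:
        mode = StrategyMode(self.mode)
        object.__setattr__(self, "mode", mode)
        if mode is StrategyMode.CURRENT:
            if self.test is not None:
                raise ValueError("the current strategy carries no new test")
        elif self.test is None:
            raise ValueError(f"mode {mode.value!r} requires a test")

    @property
    def label(self) -> str:
        if self.mode is StrategyMode.CURRENT:
            return "current"
        assert self.test is not None
        return f"{self.test.name}:{self.mode.value}"


@dataclass(frozen=True)
class RiskGroup:
    """RA / non-RA composition of one criteria-based risk stratum."""

    label: str
    n_ra: int
    n_non_ra: int

    def __post_init__(self) -> None:
        if self.n_ra < 0 or self.n_non_ra < 0:
            raise ValueError("group counts must be non-negative")

    @property
    def size(self) -> int:
        return self.n_ra + self.n_non_ra


@dataclass(frozen=True)
class RiskStratifiedCohort:
    """The three criteria strata of the reference cohort.

    ``fn_share_intermediate`` is the share of all RA patients sitting in the
    intermediate stratum (the pool an intermediate-only add-on can recover);
    ``tn_share_intermediate`` is the share of all non-RA patients there (the
    pool it can falsely convert).
    """

    high: RiskGroup
    intermediate: RiskGroup
    low: RiskGroup

    @property
    def groups(self) -> Tuple[RiskGroup, RiskGroup, RiskGroup]:
        return (self.high, self.intermediate, self.low)

    @property
    def total_n(self) -> int:
        return sum(g.size for g in self.groups)

    @property
    def total_ra(self) -> int:
        return sum(g.n_ra for g in self.groups)

    @property
    def total_non_ra(self) -> int:
        return sum(g.n_non_ra for g in self.groups)

    @property
    def fn_share_intermediate(self) -> float:
        return self.intermediate.n_ra / self.total_ra

    @property
    def tn_share_intermediate(self) -> float:
        return self.intermediate.n_non_ra / self.total_non_ra


@dataclass(frozen=True)
class ClassificationCounts:
    """TP/FP/TN/FN counts at the 12-month classification point."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("classification counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_ra(self) -> int:
        return self.tp + self.fn

    @property
    def n_non_ra(self) -> int:
        return self.fp + self.tn


#: Accuracy of the ACR/EULAR 2010 criteria against the 12-month reference
#: standard (MTX use without an alternative diagnosis).
RA2010_CRITERIA = TestAccuracy(sensitivity=0.62, specificity=0.77)


def combine_add_on_all(base: TestAccuracy, new: TestAccuracy) -> TestAccuracy:
    """Serial believe-the-positive combination when every patient is retested.

    Criteria-negative patients receive the new test; a positive on either
    classifies as RA.  Hence ``se = se_b + (1-se_b)*se_n`` and
    ``sp = sp_b * sp_n`` under conditional independence.
    """
    return TestAccuracy(
        sensitivity=base.sensitivity + (1.0 - base.sensitivity) * new.sensitivity,
        specificity=base.specificity * new.specificity,
    )


def combine_add_on_intermediate(
    base: TestAccuracy,
    new: TestAccuracy,
    fn_share_int: float,
    tn_share_int: float,
) -> TestAccuracy:
    """Combined accuracy when only the intermediate-risk stratum is retested.

    Only the share of RA patients sitting in the intermediate stratum
    (``fn_share_int``) can be recovered, and only the non-RA patients there
    (``tn_share_int``) can be falsely converted:

    ``se = se_b + fn_share_int * se_n``,
    ``sp = sp_b - tn_share_int * (1 - sp_n)``.

    With shares ``(1 - se_b, sp_b)`` - i.e. every criteria-negative patient
    sits in the intermediate stratum - this reduces exactly to
    :func:`combine_add_on_all`.
    """
    _check_prob(fn_share_int, "fn_share_int")
    _check_prob(tn_share_int, "tn_share_int")
    se = base.sensitivity + fn_share_int * new.sensitivity
    sp = base.specificity - tn_share_int * (1.0 - new.specificity)
    return TestAccuracy(sensitivity=min(se, 1.0), specificity=max(sp, 0.0))


def replacement_accuracy(new: TestAccuracy) -> TestAccuracy:
    """When the new test replaces the criteria workup, the strategy accuracy
    is the test's own accuracy."""
    return TestAccuracy(new.sensitivity, new.specificity)


def resolve_strategy_accuracy(
    strategy: StrategySpec,
    base: TestAccuracy = RA2010_CRITERIA,
    cohort: Optional[RiskStratifiedCohort] = None,
) -> TestAccuracy:
    """Resolve a strategy to its effective sensitivity/specificity.

    ``add_on_intermediate`` needs the cohort to supply the intermediate-
    stratum shares.
    """
    if strategy.mode is StrategyMode.CURRENT:
        return base
    assert strategy.test is not None
    if strategy.mode is StrategyMode.ADD_ON_ALL:
        return combine_add_on_all(base, strategy.test.accuracy)
    if strategy.mode is StrategyMode.ADD_ON_INTERMEDIATE:
        if cohort is None:
            raise ValueError("add_on_intermediate requires a cohort for its shares")
        return combine_add_on_intermediate(
            base,
            strategy.test.accuracy,
            cohort.fn_share_intermediate,
            cohort.tn_share_intermediate,
        )
    return replacement_accuracy(strategy.test.accuracy)


def reclassify_group(group: RiskGroup, test: TestAccuracy) -> Tuple[int, int]:
    """Expected (to_high, to_low) reclassification counts when ``group`` is
    retested with ``test``.

    Test-positive patients move to high risk, the rest to low risk.  Cells
    are rounded half-up independently; ``to_low`` is the complement so the
    group size is conserved.
    """
    to_high = round_half_up(
        test.sensitivity * group.n_ra + (1.0 - test.specificity) * group.n_non_ra
    )
    return to_high, group.size - to_high


def classify_cohort(
    cohort: RiskStratifiedCohort,
    strategy: StrategySpec,
    base: TestAccuracy = RA2010_CRITERIA,
) -> ClassificationCounts:
    """Expected TP/FP/TN/FN counts for a strategy applied to the cohort.

    Under the current strategy, classification is the risk stratification
    itself: the high-risk group is test-positive.  Under any new-test
    strategy, the strategy's combined accuracy is applied to the cohort's
    RA / non-RA totals (the intermediate-only shares already encode that the
    low-risk group is not retested).  TP and FP are rounded half-up; FN and
    TN are their complements so the cohort total is conserved.
    """
    if strategy.mode is StrategyMode.CURRENT:
        return ClassificationCounts(
            tp=cohort.high.n_ra,
            fp=cohort.high.n_non_ra,
            tn=cohort.intermediate.n_non_ra + cohort.low.n_non_ra,
            fn=cohort.intermediate.n_ra + cohort.low.n_ra,
        )
    acc = resolve_strategy_accuracy(strategy, base, cohort)
    tp = round_half_up(acc.sensitivity * cohort.total_ra)
    fp = round_half_up((1.0 - acc.specificity) * cohort.total_non_ra)
    return ClassificationCounts(
        tp=tp,
        fp=fp,
        tn=cohort.total_non_ra - fp,
        fn=cohort.total_ra - tp,
    )


def sample_classification_counts(
    cohort: RiskStratifiedCohort,
    strategy: StrategySpec,
    rng,
    base: TestAccuracy = RA2010_CRITERIA,
) -> ClassificationCounts:
    """Per-patient Bernoulli classification (seeded), for patient-mode runs.

    Each patient's new-test result is drawn independently; criteria status
    is fixed by the stratum (high risk = criteria-positive).
    """
    if strategy.mode is StrategyMode.CURRENT:
        return classify_cohort(cohort, strategy, base)
    assert strategy.test is not None
    se_n = strategy.test.accuracy.sensitivity
    sp_n = strategy.test.accuracy.specificity
    tp = fp = 0
    for group in cohort.groups:
        crit_pos = group.label == "high"
        if strategy.mode is StrategyMode.REPLACEMENT:
            tp += int(rng.binomial(group.n_ra, se_n))
            fp += int(rng.binomial(group.n_non_ra, 1.0 - sp_n))
        elif strategy.mode is StrategyMode.ADD_ON_ALL:
            if crit_pos:
                tp += group.n_ra
                fp += group.n_non_ra
            else:
                tp += int(rng.binomial(group.n_ra, se_n))
                fp += int(rng.binomial(group.n_non_ra, 1.0 - sp_n))
        else:  # add_on_intermediate
            if crit_pos:
                tp += group.n_ra
                fp += group.n_non_ra
            elif group.label == "intermediate":
                tp += int(rng.binomial(group.n_ra, se_n))
                fp += int(rng.binomial(group.n_non_ra, 1.0 - sp_n))
            # low risk stays negative
    return ClassificationCounts(
        tp=tp,
        fp=fp,
        tn=cohort.total_non_ra - fp,
        fn=cohort.total_ra - tp,
    )


def newly_detected_fraction(
    strategy: StrategySpec,
    base: TestAccuracy = RA2010_CRITERIA,
    cohort: Optional[RiskStratifiedCohort] = None,
) -> float:
    """Fraction of RA patients positive under the new strategy but negative
    under the current criteria (the patients who gain from early treatment).

    Under conditional independence this is ``(1-se_b)*se_n`` when all
    criteria-negative RA patients are retested (add-on all, replacement) and
    ``fn_share_int*se_n`` when only the intermediate stratum is.
    """
    if strategy.mode is StrategyMode.CURRENT:
        return 0.0
    assert strategy.test is not None
    se_n = strategy.test.accuracy.sensitivity
    if strategy.mode is StrategyMode.ADD_ON_INTERMEDIATE:
        if cohort is None:
            raise ValueError("add_on_intermediate requires a cohort")
        return cohort.fn_share_intermediate * se_n
    return (1.0 - base.sensitivity) * se_n


def tested_fraction(strategy: StrategySpec, cohort: RiskStratifiedCohort) -> float:
    """Share of the cohort administered the new test under a strategy."""
    if strategy.mode is StrategyMode.CURRENT:
        return 0.0
    if strategy.mode is StrategyMode.ADD_ON_INTERMEDIATE:
        return cohort.intermediate.size / cohort.total_n
    return 1.0
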