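"""Year-1 decision tree: classification-specific costs and QALYs.

The first model year is a decision tree that classifies every cohort
patient as TP / FP / TN / FN at 12 months.  Each classification carries a
baseline EQ-5D utility and a linear utility change over the year, so the
year-1 QALY is the trapezoidal integral ``baseline + delta / 2``.  Costs
are the diagnostic workup (plus the new test's unit cost for tested
patients), classification-specific treatment costs, and biologic DMARD
costs for a fraction of misdiagnosed (FP) patients.  Year 1 is
undiscounted; discounting starts with the state-transition phase.

At the end of the year, TP and FN patients (all RA patients) hand off to
the patient-level state-transition model with a DAS28-state entry
distribution; TN and FP patients follow the constant-utility background
track.  Patients detected only by the new strategy enter from the
untreated (FN) distribution improved by the early-detection DAS28 benefit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .cohort import PatientState, generate_patient_population
from .strategy import (
    ClassificationCounts,
    RiskStratifiedCohort,
    StrategyMode,
    StrategySpec,
    classify_cohort,
    newly_detected_fraction,
    round_half_up,
    sample_classification_counts,
    tested_fraction,
)

__all__ = [
    "FirstYearResult",
    "first_year_qaly",
    "first_year_costs",
    "apply_early_detection_benefit",
    "shift_state_distribution",
    "run_first_year",
]

_LABELS = ("TP", "FP", "TN", "FN")


@dataclass
class FirstYearResult:
    """Aggregated year-1 outcome of one strategy on the cohort.

    Per-patient costs exclude the new test's unit cost, which is carried
    separately as ``tested_fraction`` x ``test_unit_cost`` so the headroom
    analysis can remove it again.  Entry distributions describe the DAS28
    state mix with which TP / newly detected / FN patients enter the
    state-transition model.
    """

    strategy_label: str
    counts: ClassificationCounts
    cost_by_label: Dict[str, float]
    qaly_by_label: Dict[str, float]
    tested_fraction: float
    test_unit_cost: float
    n_newly_detected: int
    entry_distributions: Dict[str, List[float]]
    total_cost: float  # cohort total, incl. test costs
    total_qaly: float
    population: Optional[List[PatientState]] = field(default=None, repr=False)

    @property
    def microsim_entrants(self) -> int:
        return self.counts.tp + self.counts.fn

    @property
    def background_entrants(self) -> int:
        return self.counts.tn + self.counts.fp

    @property
    def test_cost_total(self) -> float:
        return self.tested_fraction * self.counts.total * self.test_unit_cost


def first_year_qaly(label: str, params) -> float:
    """Year-1 QALY for a classification: trapezoidal integral of the linear
    utility path, undiscounted."""
    if label not in _LABELS:
        raise ValueError(f"unknown classification label {label!r}")
    return params.baseline_utilities[label] + params.first_year_utility_deltas[label] / 2.0


def first_year_costs(
    label: str,
    strategy: StrategySpec,
    params,
    fp_biologic: str = "expectation",
) -> float:
    """Expected year-1 cost per patient of a classification, excluding the
    new test's unit cost (handled at cohort level via the tested fraction).

    The workup component is the full criteria pathway for the current and
    add-on strategies; under replacement the diagnostic component is
    dropped and only the visit component is charged.  FP patients carry
    biologic DMARD costs for the misdiagnosed fraction, in expectation or
    not at all here when handled per patient (``fp_biologic='none'``).
    """
    if label not in _LABELS:
        raise ValueError(f"unknown classification label {label!r}")
    if strategy.mode is StrategyMode.REPLACEMENT:
        workup = params.replacement_visit_cost
    else:
        workup = params.current_workup_cost
    cost = workup + params.first_year_treatment_costs[label]
    if (
        label == "FP"
        and params.fp_biologic_timing == "first_year"
        and fp_biologic == "expectation"
    ):
        cost += params.fp_biologic_fraction * params.biologic_annual_cost
    return cost


def apply_early_detection_benefit(das28: float, params) -> float:
    """Reduce a continuous DAS28 score by the early-detection benefit,
    flooring at zero."""
    if das28 < 0:
        raise ValueError("DAS28 score must be non-negative")
    return max(das28 - params.das28_benefit, 0.0)


def shift_state_distribution(
    dist: List[float], benefit: float, edges
) -> List[float]:
    """Shift a 3-state DAS28 occupancy distribution down by ``benefit``.

    Scores are uniform within each band; each band's mass is moved down by
    the benefit and re-binned, with everything below the lowest edge
    absorbed into state 1.  A zero benefit is the identity.
    """
    edges = list(edges)
    out = [0.0, 0.0, 0.0]
    for s, mass in enumerate(dist):
        if mass == 0.0:
            continue
        lo, hi = edges[s] - benefit, edges[s + 1] - benefit
        width = hi - lo
        for t in range(3):
            t_lo = edges[t] if t > 0 else -np.inf  # bottom band absorbs
            t_hi = edges[t + 1] if t < 2 else np.inf  # top band open-ended
            overlap = max(0.0, min(hi, t_hi) - max(lo, t_lo))
            out[t] += mass * overlap / width
    total = sum(out)
    return [m / total for m in out]


def run_first_year(
    cohort: RiskStratifiedCohort,
    strategy: StrategySpec,
    params,
    mode: str = "expectation",
    seed: Optional[int] = None,
) -> FirstYearResult:
    """Run the year-1 decision tree for one strategy.

    ``expectation`` mode uses deterministic expected classification counts;
    ``patient`` mode draws per-patient test results (Bernoulli) and
    per-patient FP biologic costs.  Both modes instantiate a seeded patient
    population for the state-transition hand-off; the expectation counts
    are exact in the population either way.
    """
    base = params.base_criteria
    if mode == "expectation":
        counts = classify_cohort(cohort, strategy, base)
    elif mode == "patient":
        if seed is None:
            raise ValueError("patient mode requires a seed")
        rng = np.random.default_rng(np.random.SeedSequence((seed, 12)))
        counts = sample_classification_counts(cohort, strategy, rng, base)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # patients positive under the new strategy but FN under the criteria
    counts_current = classify_cohort(
        cohort, StrategySpec(StrategyMode.CURRENT), base
    )
    if strategy.mode is StrategyMode.CURRENT:
        n_new = 0
    elif strategy.mode is StrategyMode.REPLACEMENT:
        frac = newly_detected_fraction(strategy, base, cohort)
        n_new = min(round_half_up(frac * cohort.total_ra), counts.tp)
    else:
        n_new = max(counts.tp - counts_current.tp, 0)

    cost_by_label = {
        lab: first_year_costs(lab, strategy, params) for lab in _LABELS
    }
    qaly_by_label = {lab: first_year_qaly(lab, params) for lab in _LABELS}
    tau = tested_fraction(strategy, cohort)
    unit_cost = strategy.test.unit_cost if strategy.test is not None else 0.0

    population = None
    if seed is not None:
        population = generate_patient_population(
            counts, params, seed, n_newly_detected=n_new
        )

    if mode == "patient" and population is not None:
        # per-patient FP biologic draw replaces the expectation component
        fp_cost_base = first_year_costs("FP", strategy, params, fp_biologic="none")
        total_cost = 0.0
        for p in population:
            if p.label == "FP":
                c = fp_cost_base
                if (
                    params.fp_biologic_timing == "first_year"
                    and p.u_fp_bio < params.fp_biologic_fraction
                ):
                    c += params.biologic_annual_cost
            else:
                c = cost_by_label[p.label]
            total_cost += c
    else:
        total_cost = sum(
            getattr(counts, lab.lower()) * cost_by_label[lab] for lab in _LABELS
        )
    total_cost += tau * counts.total * unit_cost
    total_qaly = sum(
        getattr(counts, lab.lower()) * qaly_by_label[lab] for lab in _LABELS
    )

    edges = params.das28_band_edges
    entry = {
        "TP": list(params.entry_state_distributions["TP"]),
        "FN": list(params.entry_state_distributions["FN"]),
        "TP_new": shift_state_distribution(
            params.entry_state_distributions["FN"], params.das28_benefit, edges
        ),
    }
    return FirstYearResult(
        strategy_label=strategy.label,
        counts=counts,
        cost_by_label=cost_by_label,
        qaly_by_label=qaly_by_label,
        tested_fraction=tau,
        test_unit_cost=unit_cost,
        n_newly_detected=n_new,
        entry_distributions=entry,
        total_cost=total_cost,
        total_qaly=total_qaly,
        population=population,
    )
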