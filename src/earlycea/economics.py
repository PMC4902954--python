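"""Cost and QALY aggregation, ICERs, net monetary benefit and headroom.

A strategy run aggregates the year-1 decision tree, the state-transition
model for RA patients and the background track for non-RA patients into
mean five-year discounted cost and QALYs per cohort patient.  Comparisons
against the current criteria-only strategy yield the incremental
cost-effectiveness ratio (ICER = dC/dE) with dominance handling, the net
monetary benefit at a willingness-to-pay threshold, and the headroom: the
maximum unit cost at which the new test would still be cost-effective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .first_year import FirstYearResult, run_first_year
from .microsim import run_background, run_microsim
from .strategy import RiskStratifiedCohort, StrategySpec

__all__ = [
    "DOMINANT",
    "DOMINATED",
    "UndefinedICERError",
    "icer",
    "nmb",
    "headroom",
    "StrategyRun",
    "run_strategy",
    "ComparisonResult",
    "compare_strategies",
]

DOMINANT = "dominant"
DOMINATED = "dominated"


class UndefinedICERError(ValueError):
    """Raised when dE = 0 with dC != 0, so the ratio carries no information."""


def icer(delta_cost: float, delta_qaly: float) -> Union[float, str]:
    """Incremental cost-effectiveness ratio with dominance labels.

    Lower costs with better outcomes is ``dominant``; higher costs with
    worse outcomes is ``dominated``.  Equal outcomes and equal costs give
    0 (the strategies are interchangeable); equal outcomes at different
    costs raise :class:`UndefinedICERError`.
    """
    if delta_qaly == 0.0:
        if delta_cost == 0.0:
            return 0.0
        raise UndefinedICERError(
            "dE = 0 with dC != 0: the ICER is undefined (strategy is "
            f"{'dominated' if delta_cost > 0 else 'dominant'} on cost alone)"
        )
    if delta_cost < 0.0 and delta_qaly > 0.0:
        return DOMINANT
    if delta_cost > 0.0 and delta_qaly < 0.0:
        return DOMINATED
    return delta_cost / delta_qaly


def nmb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Incremental net monetary benefit: wtp * dE - dC."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * delta_qaly - delta_cost


def headroom(
    delta_cost_excl_test: float,
    delta_qaly: float,
    wtp: float,
    tested_fraction: float,
) -> float:
    """Maximum unit cost per administered test at which the strategy stays
    cost-effective at the threshold.

    Solving ``(dC_excl + c * tau) / dE <= wtp`` for the unit cost c gives
    ``c* = (wtp * dE - dC_excl) / tau``.  A negative headroom means the
    strategy can never be cost-effective at any non-negative test price.
    """
    if delta_qaly <= 0:
        raise ValueError("headroom requires a QALY gain (dE > 0)")
    if not (0.0 < tested_fraction <= 1.0):
        raise ValueError("tested_fraction must be in (0, 1]")
    return (wtp * delta_qaly - delta_cost_excl_test) / tested_fraction


@dataclass
class StrategyRun:
    """Five-year outcome of one strategy on the reference cohort."""

    strategy: StrategySpec
    first_year: FirstYearResult
    total_cost: float  # cohort total, discounted EUR
    total_qaly: float
    n: int
    seed: int

    @property
    def mean_cost(self) -> float:
        return self.total_cost / self.n

    @property
    def mean_qaly(self) -> float:
        return self.total_qaly / self.n

    @property
    def mean_test_cost(self) -> float:
        """New-test spending per cohort patient."""
        return self.first_year.test_cost_total / self.n

    @property
    def label(self) -> str:
        return self.strategy.label


def run_strategy(
    cohort: RiskStratifiedCohort,
    strategy: StrategySpec,
    params,
    seed: int,
    mode: str = "expectation",
) -> StrategyRun:
    """Run the full five-year model for one strategy.

    Year 1 is the decision tree; RA patients then enter the patient-level
    state-transition model with their classification-specific entry states
    and non-RA patients the background track.  The seed drives every
    random draw; runs for different strategies with the same seed share
    per-patient randomness (common random numbers).
    """
    fy = run_first_year(cohort, strategy, params, mode=mode, seed=seed)
    assert fy.population is not None
    entrants = [p for p in fy.population if p.is_ra]
    background = [p for p in fy.population if not p.is_ra]
    ms = run_microsim(entrants, params, seed)
    bg = run_background(background, params)
    return StrategyRun(
        strategy=strategy,
        first_year=fy,
        total_cost=fy.total_cost + ms.total_cost + bg.total_cost,
        total_qaly=fy.total_qaly + ms.total_qaly + bg.total_qaly,
        n=fy.counts.total,
        seed=seed,
    )


@dataclass
class ComparisonResult:
    """One comparison row: a new strategy versus the current criteria."""

    strategy_label: str
    mean_cost: float
    mean_qaly: float
    delta_cost: float
    delta_qaly: float
    icer: Union[float, str, None]
    headroom: Optional[float]
    tested_fraction: float


def compare_strategies(
    current_run: StrategyRun, new_run: StrategyRun, params
) -> ComparisonResult:
    """Assemble the comparison of a new strategy against the current one.

    Requires both runs on the same cohort with the same seed (common
    random numbers).  Headroom removes the new test's spending from the
    cost difference and converts the remaining value at the threshold into
    a maximum price per administered test (or per cohort patient under the
    ``per_cohort`` convention).
    """
    if current_run.n != new_run.n:
        raise ValueError("runs compare different cohorts")
    if current_run.seed != new_run.seed:
        raise ValueError("runs must share the seed (common random numbers)")
    dc = new_run.mean_cost - current_run.mean_cost
    de = new_run.mean_qaly - current_run.mean_qaly
    try:
        ratio: Union[float, str, None] = icer(dc, de)
    except UndefinedICERError:
        ratio = None
    tau = new_run.first_year.tested_fraction
    head: Optional[float] = None
    if de > 0 and tau > 0:
        dc_excl = dc - new_run.mean_test_cost
        divisor = tau if params.headroom_convention == "per_test" else 1.0
        head = (params.wtp * de - dc_excl) / divisor
    return ComparisonResult(
        strategy_label=new_run.label,
        mean_cost=new_run.mean_cost,
        mean_qaly=new_run.mean_qaly,
        delta_cost=dc,
        delta_qaly=de,
        icer=ratio,
        headroom=head,
        tested_fraction=tau,
    )
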