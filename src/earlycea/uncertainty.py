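"""Probabilistic and univariate sensitivity analysis.

The PSA propagates parameter uncertainty by Monte-Carlo: each draw samples
one parameter set from the configured distributions, runs the current and
new strategies with common random numbers, and records the incremental
cost and QALY pair.  Draw clouds summarise as cost-effectiveness-plane
quadrant proportions and as the acceptability curve (CEAC): the fraction
of draws with non-negative net monetary benefit across willingness-to-pay
values.

The one-way (univariate) sensitivity analysis perturbs a single input to
its range endpoints with everything else held at base case and re-computes
the ICER, producing tornado-ordered entries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .economics import compare_strategies, run_strategy
from .parameters import ModelParameters, ParameterDistributions
from .strategy import (
    DiagnosticTest,
    RiskStratifiedCohort,
    StrategyMode,
    StrategySpec,
    TestAccuracy,
)

__all__ = [
    "PsaDraws",
    "TornadoEntry",
    "run_psa",
    "ce_plane_summary",
    "ceac",
    "default_owsa_ranges",
    "run_owsa",
]


@dataclass
class PsaDraws:
    """Incremental (cost, QALY) pairs from the Monte-Carlo PSA."""

    strategy_label: str
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    seed: int

    @property
    def n_sims(self) -> int:
        return len(self.delta_cost)


def run_psa(
    cohort: RiskStratifiedCohort,
    strategy: StrategySpec,
    params: ModelParameters,
    dists: ParameterDistributions,
    n_sims: int,
    seed: int,
    mode: str = "expectation",
) -> PsaDraws:
    """Monte-Carlo PSA of one new strategy against the current criteria.

    Per draw: sample a parameter set, run both strategies, record the
    incremental pair.  Common random numbers apply both within a draw (the
    two strategies share patient-level randomness) and across draws (every
    draw reuses the same patient-level stream), so the cloud reflects
    parameter uncertainty rather than simulation noise.  Reproducible for
    a fixed seed; degenerate distributions reproduce the base case.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    param_rng = np.random.default_rng(np.random.SeedSequence((seed, 101)))
    current = StrategySpec(StrategyMode.CURRENT)
    dc = np.empty(n_sims)
    de = np.empty(n_sims)
    for i in range(n_sims):
        params_i = dists.sample(param_rng)
        run_cur = run_strategy(cohort, current, params_i, seed, mode=mode)
        run_new = run_strategy(cohort, strategy, params_i, seed, mode=mode)
        dc[i] = run_new.mean_cost - run_cur.mean_cost
        de[i] = run_new.mean_qaly - run_cur.mean_qaly
    return PsaDraws(
        strategy_label=strategy.label, delta_cost=dc, delta_qaly=de, seed=seed
    )


def ce_plane_summary(draws: PsaDraws) -> Dict[str, float]:
    """Fractions of draws in the four cost-effectiveness-plane quadrants.

    NE: costlier and more effective; SE: cheaper (or cost-neutral) and more
    effective; NW: costlier and not more effective; SW: the rest.
    """
    if draws.n_sims == 0:
        raise ValueError("empty draw set")
    dc, de = draws.delta_cost, draws.delta_qaly
    n = draws.n_sims
    ne = float(((de > 0) & (dc > 0)).sum()) / n
    se = float(((de > 0) & (dc <= 0)).sum()) / n
    nw = float(((de <= 0) & (dc > 0)).sum()) / n
    return {"NE": ne, "SE": se, "NW": nw, "SW": 1.0 - ne - se - nw}


def ceac(draws: PsaDraws, wtp_grid: Sequence[float]) -> np.ndarray:
    """Acceptability curve: per threshold, the fraction of draws with
    non-negative net monetary benefit (wtp * dE - dC >= 0)."""
    grid = np.asarray(list(wtp_grid), dtype=float)
    if (grid < 0).any():
        raise ValueError("willingness-to-pay grid must be non-negative")
    nmb = grid[:, None] * draws.delta_qaly[None, :] - draws.delta_cost[None, :]
    return (nmb >= 0).mean(axis=1)


@dataclass
class TornadoEntry:
    """One univariate-sensitivity bar: the ICER at both range endpoints."""

    parameter: str
    low: float
    high: float
    icer_low: Union[float, str]
    icer_high: Union[float, str]
    icer_base: Union[float, str]
    raw_low: float  # dC/dE regardless of dominance labelling, for ordering
    raw_high: float

    @property
    def span(self) -> float:
        return abs(self.raw_high - self.raw_low)


def default_owsa_ranges(strategy: StrategySpec, params: ModelParameters) -> Dict[str, Tuple[float, float]]:
    """Default one-way ranges: test sensitivity and specificity from 0.50
    to 1.00, test cost from zero to double, the early-detection DAS28
    benefit from 0 to 0.6, and the misdiagnosed-biologic fraction from 0 to
    20 %."""
    assert strategy.test is not None
    return {
        "sensitivity": (0.50, 1.00),
        "specificity": (0.50, 1.00),
        "unit_cost": (0.0, 2.0 * strategy.test.unit_cost),
        "das28_benefit": (0.0, 0.6),
        "fp_biologic_fraction": (0.0, 0.20),
    }


_STRATEGY_PARAMS = ("sensitivity", "specificity", "unit_cost")


def _evaluate_icer(
    cohort: RiskStratifiedCohort,
    strategy: StrategySpec,
    params: ModelParameters,
    seed: int,
    mode: str,
) -> Tuple[Union[float, str, None], float]:
    current = StrategySpec(StrategyMode.CURRENT)
    run_cur = run_strategy(cohort, current, params, seed, mode=mode)
    run_new = run_strategy(cohort, strategy, params, seed, mode=mode)
    cmp = compare_strategies(run_cur, run_new, params)
    raw = cmp.delta_cost / cmp.delta_qaly if cmp.delta_qaly != 0 else np.nan
    return cmp.icer, raw


def _with_override(
    strategy: StrategySpec, params: ModelParameters, name: str, value: float
) -> Tuple[StrategySpec, ModelParameters]:
    if name in _STRATEGY_PARAMS:
        assert strategy.test is not None
        test = strategy.test
        if name == "unit_cost":
            new_test = DiagnosticTest(test.name, test.accuracy, value)
        else:
            acc = {
                "sensitivity": test.accuracy.sensitivity,
                "specificity": test.accuracy.specificity,
            }
            acc[name] = value
            new_test = DiagnosticTest(test.name, TestAccuracy(**acc), test.unit_cost)
        return dc_replace(strategy, test=new_test), params
    return strategy, params.replace(**{name: value})


def run_owsa(
    cohort: RiskStratifiedCohort,
    strategy: StrategySpec,
    params: ModelParameters,
    seed: int,
    ranges: Optional[Dict[str, Tuple[float, float]]] = None,
    mode: str = "expectation",
) -> List[TornadoEntry]:
    """One-way sensitivity analysis over the configured ranges.

    Each parameter is set to its low and high endpoint in turn with all
    other inputs at base case and the same simulation seed; entries come
    back sorted by ICER span (tornado order).
    """
    if ranges is None:
        ranges = default_owsa_ranges(strategy, params)
    icer_base, _ = _evaluate_icer(cohort, strategy, params, seed, mode)
    entries: List[TornadoEntry] = []
    for name, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValueError(f"range for {name!r} is inverted")
        results = []
        for value in (lo, hi):
            s2, p2 = _with_override(strategy, params, name, value)
            results.append(_evaluate_icer(cohort, s2, p2, seed, mode))
        entries.append(
            TornadoEntry(
                parameter=name,
                low=lo,
                high=hi,
                icer_low=results[0][0],
                icer_high=results[1][0],
                icer_base=icer_base,
                raw_low=results[0][1],
                raw_high=results[1][1],
            )
        )
    entries.sort(key=lambda e: e.span, reverse=True)
    return entries
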