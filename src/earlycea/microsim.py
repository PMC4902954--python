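"""Years 2-5: patient-level DAS28 state-transition model and background track.

RA patients (TP and FN at 12 months) move between three disease-activity
states - remission (DAS28 <= 2.6), low (2.6 < DAS28 <= 3.2) and
moderate/severe (> 3.2) - in 3-month cycles over four years (16 cycles).
Patients whose DAS28 exceeds 3.2 at 12 months or any later cycle become
(stickily) eligible for biologic DMARDs; among eligible patients not yet
on a biologic, a 2 % per-cycle start probability is distributed over the
current states with 1-3-6 weights.  Once started, patients stay on the
biologic (a cost-neutral switch between agents is not an event) and follow
the biologic-stratum transition matrix and utilities.

TN and FP patients follow a background track with constant utility and no
RA-related costs (the misdiagnosis biologic cost is a year-1 or first
background-year charge depending on configuration).

Costs discount at 4 %/year and effects at 1.5 %/year (differential
discounting), with cycle flows discounted at their cycle-start time; no
half-cycle correction and no death state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .cohort import PatientState

__all__ = [
    "TransitionModel",
    "MicrosimResult",
    "BackgroundResult",
    "convert_probability",
    "step_patient",
    "biologic_start_step",
    "cycle_accrual",
    "run_background",
    "run_microsim",
]


@dataclass(frozen=True)
class TransitionModel:
    """Per-cycle 3x3 transition matrices for the two biologic strata."""

    nonbio: np.ndarray
    bio: np.ndarray

    def __post_init__(self) -> None:
        for name in ("nonbio", "bio"):
            mat = np.asarray(getattr(self, name), dtype=float)
            if mat.shape != (3, 3) or (mat < 0).any() or not np.allclose(
                mat.sum(axis=1), 1.0, atol=1e-9
            ):
                raise ValueError(f"{name} must be a row-stochastic 3x3 matrix")
            object.__setattr__(self, name, mat)

    @classmethod
    def from_params(cls, params) -> "TransitionModel":
        return cls(
            nonbio=np.asarray(params.transition_matrix_nonbio, dtype=float),
            bio=np.asarray(params.transition_matrix_bio, dtype=float),
        )


def convert_probability(p: float, period_months: float, cycle_months: float) -> float:
    """Convert a probability over one period to another under a constant
    rate: ``1 - (1-p)^(cycle/period)``.

    The model's canonical use converts the 15 % biologic uptake observed
    over 24 months into the ~2 % per-3-month start probability.
    """
    if not (0.0 <= p < 1.0):
        raise ValueError("p must be in [0, 1); p = 1 implies an infinite rate")
    if period_months <= 0 or cycle_months <= 0:
        raise ValueError("periods must be positive")
    return 1.0 - (1.0 - p) ** (cycle_months / period_months)


def step_patient(patient: PatientState, transitions: TransitionModel, rng) -> PatientState:
    """Draw the patient's next DAS28 state from the matrix row of their
    biologic stratum (in place; returns the patient)."""
    if patient.das28_state not in (1, 2, 3):
        raise ValueError(f"invalid DAS28 state {patient.das28_state!r}")
    mat = transitions.bio if patient.on_biologic else transitions.nonbio
    row = mat[patient.das28_state - 1]
    u = rng.random()
    patient.das28_state = int(np.searchsorted(np.cumsum(row), u, side="right")) + 1
    patient.das28_state = min(patient.das28_state, 3)
    return patient


def _start_probabilities(
    states: np.ndarray, candidates: np.ndarray, params
) -> np.ndarray:
    """Per-patient biologic start probability for this cycle.

    Under the ``weighted`` convention the overall per-cycle start
    probability among eligible candidates equals the configured 2 %, and is
    distributed over their current states proportional to the 1-3-6
    weights.  Under ``state3_only`` only candidates currently in state 3
    start, each with the configured probability.
    """
    p0 = params.biologic_cycle_start_prob
    probs = np.zeros(states.shape, dtype=float)
    if not candidates.any():
        return probs
    if params.biologic_start_convention == "state3_only":
        probs[candidates & (states == 3)] = p0
        return probs
    weights = np.asarray(params.biologic_alloc_weights, dtype=float)
    if (weights <= 0).any():
        raise ValueError("biologic_alloc_weights must be positive")
    occ = np.array([(candidates & (states == s)).sum() for s in (1, 2, 3)])
    denom = float(occ @ weights)
    if denom == 0.0:
        return probs
    per_state = np.minimum(p0 * weights * occ.sum() / denom, 1.0)
    probs[candidates] = per_state[states[candidates] - 1]
    return probs


def biologic_start_step(patients: List[PatientState], params, rng) -> List[PatientState]:
    """One cycle of biologic DMARD starts over a patient list (in place).

    Eligibility is sticky: any patient observed in state 3 at entry or
    since stays eligible.  Starts are drawn per patient with the per-state
    probabilities of :func:`_start_probabilities`; once on a biologic a
    patient never discontinues.
    """
    states = np.array([p.das28_state or 0 for p in patients])
    for p in patients:
        if p.das28_state == 3:
            p.ever_eligible = True
    candidates = np.array(
        [p.ever_eligible and not p.on_biologic for p in patients], dtype=bool
    )
    probs = _start_probabilities(states, candidates, params)
    u = rng.random(len(patients))
    for i, p in enumerate(patients):
        if candidates[i] and u[i] < probs[i]:
            p.on_biologic = True
    return patients


def cycle_accrual(patient: PatientState, params, cycle_index: int) -> Tuple[float, float]:
    """Discounted (cost, QALY) increment for one patient-cycle.

    ``cycle_index`` counts state-transition cycles from 0 (the first cycle
    after year 1, starting at t = 1 year).
    """
    s = patient.das28_state
    if s not in (1, 2, 3):
        raise ValueError(f"invalid DAS28 state {s!r}")
    t = 1.0 + cycle_index * params.cycle_years
    df_cost = params.discount_factor(t, params.discount_costs)
    df_eff = params.discount_factor(t, params.discount_effects)
    cost = params.state_costs_direct[s - 1] + params.state_costs_productivity[s - 1]
    if patient.on_biologic:
        cost += params.biologic_annual_cost * params.cycle_years
    qaly = (
        params.utility(s, patient.on_biologic, patient.dip_prone) * params.cycle_years
    )
    return cost * df_cost, qaly * df_eff


@dataclass
class MicrosimResult:
    """Per-patient discounted accumulators and cycle-level occupancy."""

    ids: np.ndarray
    costs: np.ndarray
    qalys: np.ndarray
    final_states: np.ndarray
    on_biologic: np.ndarray
    occupancy: np.ndarray  # (n_cycles, 3) state counts per cycle
    biologic_per_cycle: np.ndarray  # patients on biologic at each cycle
    trajectories: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def total_cost(self) -> float:
        return float(self.costs.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.qalys.sum())

    @property
    def n(self) -> int:
        return len(self.ids)


def run_microsim(
    entrants: Sequence[PatientState],
    params,
    seed: int,
    collect_trajectories: bool = False,
) -> MicrosimResult:
    """Simulate the state-transition phase for RA entrants (TP and FN).

    Vectorised over patients with one uniform per patient-cycle for the
    biologic start and one for the transition, pre-drawn from a single
    seeded generator keyed by patient position - so two runs with the same
    seed and aligned populations share randomness patient-for-patient
    (common random numbers).

    Within each cycle: eligibility update, biologic starts, cost/QALY
    accrual for the cycle, then the state transition.
    """
    entrants = list(entrants)
    for p in entrants:
        if not p.is_ra:
            raise ValueError("only TP/FN patients enter the state-transition model")
        if p.das28_state not in (1, 2, 3):
            raise ValueError("entrants must carry a valid DAS28 entry state")
    n = len(entrants)
    n_cycles = params.n_cycles
    tm = TransitionModel.from_params(params)
    cum_nonbio = np.cumsum(tm.nonbio, axis=1)
    cum_bio = np.cumsum(tm.bio, axis=1)

    rng = np.random.default_rng(np.random.SeedSequence((seed, 77)))
    u_bio = rng.random((n, n_cycles))
    u_trans = rng.random((n, n_cycles))

    states = np.array([p.das28_state for p in entrants], dtype=int)
    dip = np.array([p.dip_prone for p in entrants], dtype=bool)
    on_bio = np.array([p.on_biologic for p in entrants], dtype=bool)
    eligible = np.array([p.ever_eligible for p in entrants], dtype=bool)

    costs = np.zeros(n)
    qalys = np.zeros(n)
    occupancy = np.zeros((n_cycles, 3), dtype=int)
    bio_per_cycle = np.zeros(n_cycles, dtype=int)
    traj = np.zeros((n, n_cycles), dtype=int) if collect_trajectories else None

    direct = np.asarray(params.state_costs_direct, dtype=float)
    prod = np.asarray(params.state_costs_productivity, dtype=float)
    # utility lookup [on_bio, dip, state-1]
    util = np.empty((2, 2, 3))
    for b, stratum in enumerate(("non_biologic", "biologic")):
        for d, mixture in enumerate(("typical", "dip_prone")):
            util[b, d] = params.state_utilities[stratum][mixture]

    for k in range(n_cycles):
        eligible |= states == 3
        candidates = eligible & ~on_bio
        probs = _start_probabilities(states, candidates, params)
        on_bio |= candidates & (u_bio[:, k] < probs)

        t = 1.0 + k * params.cycle_years
        df_cost = params.discount_factor(t, params.discount_costs)
        df_eff = params.discount_factor(t, params.discount_effects)
        cycle_cost = direct[states - 1] + prod[states - 1]
        cycle_cost = cycle_cost + on_bio * (
            params.biologic_annual_cost * params.cycle_years
        )
        costs += cycle_cost * df_cost
        qalys += (
            util[on_bio.astype(int), dip.astype(int), states - 1]
            * params.cycle_years
            * df_eff
        )

        occupancy[k] = [(states == s).sum() for s in (1, 2, 3)]
        bio_per_cycle[k] = int(on_bio.sum())
        if traj is not None:
            traj[:, k] = states

        cum = np.where(on_bio[:, None], cum_bio[states - 1], cum_nonbio[states - 1])
        u = u_trans[:, k, None]
        states = 1 + (u > cum[:, :1]).ravel().astype(int) + (
            u > cum[:, 1:2]
        ).ravel().astype(int)

    for p, c, q, s, b, e in zip(entrants, costs, qalys, states, on_bio, eligible):
        p.cum_cost += float(c)
        p.cum_qaly += float(q)
        p.das28_state = int(s)
        p.on_biologic = bool(b)
        p.ever_eligible = bool(e)

    return MicrosimResult(
        ids=np.array([p.id for p in entrants]),
        costs=costs,
        qalys=qalys,
        final_states=states,
        on_biologic=on_bio,
        occupancy=occupancy,
        biologic_per_cycle=bio_per_cycle,
        trajectories=traj,
    )


@dataclass
class BackgroundResult:
    n: int
    total_cost: float
    total_qaly: float


def run_background(patients: Sequence[PatientState], params) -> BackgroundResult:
    """Background track for TN/FP patients: constant utility, no RA-related
    costs except (optionally) the misdiagnosis biologic charge spread over
    the first background year."""
    patients = list(patients)
    for p in patients:
        if p.is_ra:
            raise ValueError("only TN/FP patients follow the background track")
    n = len(patients)
    n_fp = sum(1 for p in patients if p.label == "FP")
    total_cost = 0.0
    total_qaly = 0.0
    cycles_per_year = int(round(1.0 / params.cycle_years))
    for k in range(params.n_cycles):
        t = 1.0 + k * params.cycle_years
        df_eff = params.discount_factor(t, params.discount_effects)
        total_qaly += n * params.background_utility * params.cycle_years * df_eff
        if params.fp_biologic_timing == "background" and k < cycles_per_year:
            df_cost = params.discount_factor(t, params.discount_costs)
            total_cost += (
                n_fp
                * params.fp_biologic_fraction
                * params.biologic_annual_cost
                * params.cycle_years
                * df_cost
            )
    per_patient_qaly = total_qaly / n if n else 0.0
    for p in patients:
        p.cum_qaly += per_patient_qaly
    return BackgroundResult(n=n, total_cost=total_cost, total_qaly=total_qaly)
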