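"""Model parameters, the shipped defaults, and PSA sampling distributions.

All downstream stages read a single validated :class:`ModelParameters`
object.  Defaults ship in ``data/default_parameters.yaml``; every entry in
that file is annotated ``source: paper`` (a value printed in the source
study) or ``source: fixture`` (a documented stand-in for quantities the
study took from its supplementary material or unpublished cohort data -
transition matrices, per-state costs, utility tables, entry-state
distributions).  Code never distinguishes the two: drop in better numbers
and everything downstream follows.

For probabilistic sensitivity analysis, probability- and utility-like
parameters get beta-family laws (Dirichlet for simplexes and matrix rows),
cost-like parameters get gamma laws; means always equal the base-case
values.  Test sensitivity/specificity/cost are held fixed, mirroring the
early-assessment convention of evaluating hypothetical tests at their
nominal operating points.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .strategy import RiskStratifiedCohort, TestAccuracy

__all__ = [
    "ModelParameters",
    "ParameterDistributions",
    "default_parameters",
    "load_parameters",
    "save_parameters",
    "psa_distributions",
]

_LABELS = ("TP", "FP", "TN", "FN")
_MIN_UTILITY = -0.59  # floor of the EQ-5D-3L value set


@dataclass
class ModelParameters:
    """Complete parameter set of the five-year model.

    Probabilities are per the period stated in the field name; costs are
    EUR (2014 price level); utilities are EQ-5D index values.
    """

    # diagnostic layer
    base_criteria: TestAccuracy
    cohort: Optional[RiskStratifiedCohort]
    prevalence_12m: float
    # model frame
    horizon_years: int
    cycle_months: int
    das28_cuts: Tuple[float, float]
    das28_band_edges: Tuple[float, float, float, float]
    # biologic DMARD uptake
    biologic_uptake_24m: float
    biologic_cycle_start_prob: float
    biologic_alloc_weights: Tuple[float, float, float]
    biologic_start_convention: str  # "weighted" | "state3_only"
    biologic_annual_cost: float
    fp_biologic_fraction: float
    fp_biologic_timing: str  # "first_year" | "background"
    # first-year utilities
    baseline_utilities: Dict[str, float]
    first_year_utility_deltas: Dict[str, float]
    background_utility: float
    dip_prone_fraction: float
    dip_threshold: float
    das28_benefit: float
    # economics
    discount_costs: float
    discount_effects: float
    wtp: float
    headroom_convention: str  # "per_test" | "per_cohort"
    # first-year costs
    current_workup_cost: float
    replacement_visit_cost: float
    first_year_treatment_costs: Dict[str, float]
    # state-transition model (fixture-backed)
    entry_state_distributions: Dict[str, List[float]]
    transition_matrix_nonbio: List[List[float]]
    transition_matrix_bio: List[List[float]]
    state_costs_direct: List[float]
    state_costs_productivity: List[float]
    state_utilities: Dict[str, Dict[str, List[float]]]
    # PSA spread conventions
    psa_beta_concentration: float
    psa_gamma_cv: float
    # provenance annotations (field name -> "paper" | "fixture")
    sources: Dict[str, str] = field(default_factory=dict)

    # -- derived helpers -------------------------------------------------
    @property
    def n_cycles(self) -> int:
        """Cycles in the state-transition phase (years 2..horizon)."""
        return (self.horizon_years - 1) * 12 // self.cycle_months

    @property
    def cycle_years(self) -> float:
        return self.cycle_months / 12.0

    def utility(self, state: int, on_biologic: bool, dip_prone: bool) -> float:
        stratum = "biologic" if on_biologic else "non_biologic"
        mixture = "dip_prone" if dip_prone else "typical"
        return self.state_utilities[stratum][mixture][state - 1]

    def discount_factor(self, t_years: float, rate: float) -> float:
        """Year-1 flows are undiscounted; later flows discount at (1+r)^-t."""
        if t_years < 1.0:
            return 1.0
        return (1.0 + rate) ** (-t_years)

    # -- validation ------------------------------------------------------
    def validate(self) -> "ModelParameters":
        def prob(x, name):
            if not (0.0 <= x <= 1.0):
                raise ValueError(f"{name} must be a probability, got {x!r}")

        prob(self.prevalence_12m, "prevalence_12m")
        prob(self.biologic_uptake_24m, "biologic_uptake_24m")
        prob(self.biologic_cycle_start_prob, "biologic_cycle_start_prob")
        prob(self.fp_biologic_fraction, "fp_biologic_fraction")
        prob(self.dip_prone_fraction, "dip_prone_fraction")
        if any(w <= 0 for w in self.biologic_alloc_weights):
            raise ValueError("biologic_alloc_weights must be positive")
        if self.biologic_start_convention not in ("weighted", "state3_only"):
            raise ValueError(
                f"unknown biologic_start_convention {self.biologic_start_convention!r}"
            )
        if self.fp_biologic_timing not in ("first_year", "background"):
            raise ValueError(f"unknown fp_biologic_timing {self.fp_biologic_timing!r}")
        if self.headroom_convention not in ("per_test", "per_cohort"):
            raise ValueError(
                f"unknown headroom_convention {self.headroom_convention!r}"
            )
        if not (self.das28_cuts[0] < self.das28_cuts[1]):
            raise ValueError("das28_cuts must be increasing")
        if list(self.das28_band_edges) != sorted(self.das28_band_edges):
            raise ValueError("das28_band_edges must be non-decreasing")
        for label in _LABELS:
            u = self.baseline_utilities[label]
            if not (_MIN_UTILITY <= u <= 1.0):
                raise ValueError(f"baseline utility for {label} out of range: {u}")
            if self.first_year_treatment_costs[label] < 0:
                raise ValueError("first-year treatment costs must be >= 0")
        for name, mat in (
            ("transition_matrix_nonbio", self.transition_matrix_nonbio),
            ("transition_matrix_bio", self.transition_matrix_bio),
        ):
            arr = np.asarray(mat, dtype=float)
            if arr.shape != (3, 3) or (arr < 0).any():
                raise ValueError(f"{name} must be a non-negative 3x3 matrix")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")
        for label, dist in self.entry_state_distributions.items():
            arr = np.asarray(dist, dtype=float)
            if arr.shape != (3,) or (arr < 0).any() or not np.isclose(arr.sum(), 1.0):
                raise ValueError(f"entry distribution for {label} is not a simplex")
        for costs in (self.state_costs_direct, self.state_costs_productivity):
            if len(costs) != 3 or any(c < 0 for c in costs):
                raise ValueError("state costs must be three non-negative values")
        for stratum in self.state_utilities.values():
            for mix in stratum.values():
                if len(mix) != 3 or any(
                    not (_MIN_UTILITY <= u <= 1.0) for u in mix
                ):
                    raise ValueError("state utilities out of EQ-5D range")
        for c in (
            self.biologic_annual_cost,
            self.current_workup_cost,
            self.replacement_visit_cost,
            self.wtp,
        ):
            if c < 0:
                raise ValueError("costs and the WTP threshold must be >= 0")
        return self

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> Dict[str, Any]:
        d: Dict[str, Any] = {
            "base_criteria": {
                "sensitivity": self.base_criteria.sensitivity,
                "specificity": self.base_criteria.specificity,
            },
            "prevalence_12m": self.prevalence_12m,
            "horizon_years": self.horizon_years,
            "cycle_months": self.cycle_months,
            "das28_cuts": list(self.das28_cuts),
            "das28_band_edges": list(self.das28_band_edges),
            "biologic_uptake_24m": self.biologic_uptake_24m,
            "biologic_cycle_start_prob": self.biologic_cycle_start_prob,
            "biologic_alloc_weights": list(self.biologic_alloc_weights),
            "biologic_start_convention": self.biologic_start_convention,
            "biologic_annual_cost": self.biologic_annual_cost,
            "fp_biologic_fraction": self.fp_biologic_fraction,
            "fp_biologic_timing": self.fp_biologic_timing,
            "baseline_utilities": dict(self.baseline_utilities),
            "first_year_utility_deltas": dict(self.first_year_utility_deltas),
            "background_utility": self.background_utility,
            "dip_prone_fraction": self.dip_prone_fraction,
            "dip_threshold": self.dip_threshold,
            "das28_benefit": self.das28_benefit,
            "discount_costs": self.discount_costs,
            "discount_effects": self.discount_effects,
            "wtp": self.wtp,
            "headroom_convention": self.headroom_convention,
            "current_workup_cost": self.current_workup_cost,
            "replacement_visit_cost": self.replacement_visit_cost,
            "first_year_treatment_costs": dict(self.first_year_treatment_costs),
            "entry_state_distributions": {
                k: list(v) for k, v in self.entry_state_distributions.items()
            },
            "transition_matrix_nonbio": [list(r) for r in self.transition_matrix_nonbio],
            "transition_matrix_bio": [list(r) for r in self.transition_matrix_bio],
            "state_costs_direct": list(self.state_costs_direct),
            "state_costs_productivity": list(self.state_costs_productivity),
            "state_utilities": {
                s: {m: list(v) for m, v in mixes.items()}
                for s, mixes in self.state_utilities.items()
            },
            "psa_beta_concentration": self.psa_beta_concentration,
            "psa_gamma_cv": self.psa_gamma_cv,
        }
        if self.cohort is not None:
            d["cohort"] = {
                g.label: {"n_ra": g.n_ra, "n_non_ra": g.n_non_ra}
                for g in self.cohort.groups
            }
        return d

    @classmethod
    def from_dict(
        cls, d: Dict[str, Any], sources: Optional[Dict[str, str]] = None
    ) -> "ModelParameters":
        from .strategy import RiskGroup  # local to avoid cycle at import time

        cohort = None
        if "cohort" in d:
            cd = d["cohort"]
            cohort = RiskStratifiedCohort(
                high=RiskGroup("high", **cd["high"]),
                intermediate=RiskGroup("intermediate", **cd["intermediate"]),
                low=RiskGroup("low", **cd["low"]),
            )
        return cls(
            base_criteria=TestAccuracy(**d["base_criteria"]),
            cohort=cohort,
            prevalence_12m=d["prevalence_12m"],
            horizon_years=d["horizon_years"],
            cycle_months=d["cycle_months"],
            das28_cuts=tuple(d["das28_cuts"]),
            das28_band_edges=tuple(d["das28_band_edges"]),
            biologic_uptake_24m=d["biologic_uptake_24m"],
            biologic_cycle_start_prob=d["biologic_cycle_start_prob"],
            biologic_alloc_weights=tuple(d["biologic_alloc_weights"]),
            biologic_start_convention=d["biologic_start_convention"],
            biologic_annual_cost=d["biologic_annual_cost"],
            fp_biologic_fraction=d["fp_biologic_fraction"],
            fp_biologic_timing=d["fp_biologic_timing"],
            baseline_utilities=dict(d["baseline_utilities"]),
            first_year_utility_deltas=dict(d["first_year_utility_deltas"]),
            background_utility=d["background_utility"],
            dip_prone_fraction=d["dip_prone_fraction"],
            dip_threshold=d["dip_threshold"],
            das28_benefit=d["das28_benefit"],
            discount_costs=d["discount_costs"],
            discount_effects=d["discount_effects"],
            wtp=d["wtp"],
            headroom_convention=d["headroom_convention"],
            current_workup_cost=d["current_workup_cost"],
            replacement_visit_cost=d["replacement_visit_cost"],
            first_year_treatment_costs=dict(d["first_year_treatment_costs"]),
            entry_state_distributions={
                k: list(v) for k, v in d["entry_state_distributions"].items()
            },
            transition_matrix_nonbio=[list(r) for r in d["transition_matrix_nonbio"]],
            transition_matrix_bio=[list(r) for r in d["transition_matrix_bio"]],
            state_costs_direct=list(d["state_costs_direct"]),
            state_costs_productivity=list(d["state_costs_productivity"]),
            state_utilities={
                s: {m: list(v) for m, v in mixes.items()}
                for s, mixes in d["state_utilities"].items()
            },
            psa_beta_concentration=d["psa_beta_concentration"],
            psa_gamma_cv=d["psa_gamma_cv"],
            sources=dict(sources or {}),
        ).validate()

    def replace(self, **updates: Any) -> "ModelParameters":
        """Return a validated copy with top-level fields replaced."""
        d = self.to_dict()
        cohort = updates.pop("cohort", self.cohort)
        for key, value in updates.items():
            if key not in d:
                raise KeyError(f"unknown parameter {key!r}")
            d[key] = value
        d.pop("cohort", None)
        out = ModelParameters.from_dict(d, sources=self.sources)
        out.cohort = cohort
        return out

    def param_hash(self) -> str:
        """Stable digest of the full parameter set (cohort included)."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _read_annotated(doc: Dict[str, Any]) -> Tuple[Dict[str, Any], Dict[str, str]]:
    """Split an annotated YAML document into values and source tags.

    Each top-level entry must be a mapping ``{value: ..., source: paper|fixture}``.
    """
    values: Dict[str, Any] = {}
    sources: Dict[str, str] = {}
    for key, entry in doc.items():
        if not isinstance(entry, dict) or "value" not in entry or "source" not in entry:
            raise ValueError(
                f"parameter {key!r} must be a mapping with 'value' and 'source'"
            )
        if entry["source"] not in ("paper", "fixture"):
            raise ValueError(
                f"parameter {key!r} has source {entry['source']!r}; "
                "expected 'paper' or 'fixture'"
            )
        values[key] = entry["value"]
        sources[key] = entry["source"]
    return values, sources


def load_parameters(path) -> ModelParameters:
    """Load and validate an annotated parameter file (YAML)."""
    with open(path, "r") as fh:
        doc = yaml.safe_load(fh)
    values, sources = _read_annotated(doc)
    return ModelParameters.from_dict(values, sources=sources)


def save_parameters(params: ModelParameters, path) -> None:
    """Write the annotated parameter file back out (round-trips with
    :func:`load_parameters`)."""
    d = params.to_dict()
    doc = {
        key: {"value": value, "source": params.sources.get(key, "fixture")}
        for key, value in d.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_parameters(with_cohort: bool = True) -> ModelParameters:
    """The shipped default parameter set, with the derived reference cohort
    attached unless ``with_cohort`` is False."""
    ref = resources.files("earlycea.data").joinpath("default_parameters.yaml")
    with resources.as_file(ref) as path:
        params = load_parameters(path)
    if with_cohort:
        from .cohort import derive_reference_cohort

        params.cohort = derive_reference_cohort()
    return params


# ---------------------------------------------------------------------------
# PSA distributions
# ---------------------------------------------------------------------------


class Degenerate:
    """Point mass; used for fixed parameters and zero-variance settings."""

    def __init__(self, value):
        self.value = value

    @property
    def mean(self):
        return self.value

    def sample(self, rng) -> Any:
        return copy.deepcopy(self.value)


class BetaLaw:
    """Beta with given mean and concentration kappa (alpha+beta=kappa)."""

    def __init__(self, mean: float, concentration: float):
        if not (0.0 < mean < 1.0):
            raise ValueError("beta mean must lie strictly inside (0, 1)")
        self.mean_value = mean
        self.concentration = concentration

    @property
    def mean(self) -> float:
        return self.mean_value

    def sample(self, rng) -> float:
        if not np.isfinite(self.concentration):
            return self.mean_value
        a = self.mean_value * self.concentration
        b = (1.0 - self.mean_value) * self.concentration
        return float(rng.beta(a, b))


class ScaledBetaLaw:
    """Beta rescaled to [lo, hi]; for utilities that may sit below 0 or
    (dip-prone mixture) below the 0.50 dip threshold."""

    def __init__(self, mean: float, lo: float, hi: float, concentration: float):
        if not (lo < mean < hi):
            raise ValueError("scaled-beta mean must lie inside (lo, hi)")
        self.mean_value = mean
        self.lo = lo
        self.hi = hi
        self.concentration = concentration

    @property
    def mean(self) -> float:
        return self.mean_value

    def sample(self, rng) -> float:
        if not np.isfinite(self.concentration):
            return self.mean_value
        m = (self.mean_value - self.lo) / (self.hi - self.lo)
        a = m * self.concentration
        b = (1.0 - m) * self.concentration
        return self.lo + (self.hi - self.lo) * float(rng.beta(a, b))


class GammaLaw:
    """Gamma with given mean and coefficient of variation."""

    def __init__(self, mean: float, cv: float):
        if mean <= 0:
            raise ValueError("gamma mean must be positive")
        self.mean_value = mean
        self.cv = cv

    @property
    def mean(self) -> float:
        return self.mean_value

    def sample(self, rng) -> float:
        if self.cv == 0:
            return self.mean_value
        shape = 1.0 / (self.cv**2)
        scale = self.mean_value / shape
        return float(rng.gamma(shape, scale))


class DirichletLaw:
    """Dirichlet with mean equal to the base simplex."""

    def __init__(self, probs: Sequence[float], concentration: float):
        self.probs = np.asarray(probs, dtype=float)
        self.concentration = concentration

    @property
    def mean(self):
        return list(self.probs)

    def sample(self, rng) -> List[float]:
        if not np.isfinite(self.concentration):
            return list(self.probs)
        alpha = np.clip(self.probs * self.concentration, 1e-6, None)
        return list(map(float, rng.dirichlet(alpha)))


def _set_path(d: Dict[str, Any], path: str, value: Any) -> None:
    parts = path.split(".")
    node = d
    for part in parts[:-1]:
        node = node[int(part)] if isinstance(node, list) else node[part]
    last = parts[-1]
    if isinstance(node, list):
        node[int(last)] = value
    else:
        node[last] = value


@dataclass
class ParameterDistributions:
    """Per-parameter sampling laws for the PSA, keyed by dotted path into
    the parameter dictionary."""

    base: ModelParameters
    laws: Dict[str, Any]

    def sample(self, rng) -> ModelParameters:
        d = self.base.to_dict()
        d.pop("cohort", None)
        for path, law in self.laws.items():
            _set_path(d, path, law.sample(rng))
        out = ModelParameters.from_dict(d, sources=self.base.sources)
        out.cohort = self.base.cohort
        return out

    def means(self) -> Dict[str, Any]:
        return {path: law.mean for path, law in self.laws.items()}


def psa_distributions(params: ModelParameters) -> ParameterDistributions:
    """Build the PSA distribution set from a parameter object.

    Beta/Dirichlet for probabilities, utilities and stochastic matrix rows;
    gamma for costs; degenerate for structurally fixed quantities (test
    accuracies and unit costs are fixed upstream and never appear here).
    Spread is controlled by ``psa_beta_concentration`` (Dirichlet/beta
    kappa) and ``psa_gamma_cv``; a concentration of ``inf`` together with a
    CV of 0 makes every draw equal the base case.
    """
    k = params.psa_beta_concentration
    cv = params.psa_gamma_cv
    laws: Dict[str, Any] = {}

    for label in _LABELS:
        laws[f"baseline_utilities.{label}"] = BetaLaw(
            params.baseline_utilities[label], k
        )
    laws["background_utility"] = BetaLaw(params.background_utility, k)
    laws["dip_prone_fraction"] = BetaLaw(params.dip_prone_fraction, k)
    laws["fp_biologic_fraction"] = BetaLaw(params.fp_biologic_fraction, k)
    laws["biologic_cycle_start_prob"] = BetaLaw(params.biologic_cycle_start_prob, k)

    for label, dist in params.entry_state_distributions.items():
        laws[f"entry_state_distributions.{label}"] = DirichletLaw(dist, k)
    for name, mat in (
        ("transition_matrix_nonbio", params.transition_matrix_nonbio),
        ("transition_matrix_bio", params.transition_matrix_bio),
    ):
        for i, row in enumerate(mat):
            laws[f"{name}.{i}"] = DirichletLaw(row, k)

    for stratum, mixes in params.state_utilities.items():
        for mixture, values in mixes.items():
            lo = _MIN_UTILITY if mixture == "dip_prone" else 0.0
            for i, u in enumerate(values):
                laws[f"state_utilities.{stratum}.{mixture}.{i}"] = ScaledBetaLaw(
                    u, lo, 1.0, k
                )

    def cost_law(value: float):
        return GammaLaw(value, cv) if value > 0 else Degenerate(value)

    laws["current_workup_cost"] = cost_law(params.current_workup_cost)
    laws["replacement_visit_cost"] = cost_law(params.replacement_visit_cost)
    laws["biologic_annual_cost"] = cost_law(params.biologic_annual_cost)
    for label in _LABELS:
        laws[f"first_year_treatment_costs.{label}"] = cost_law(
            params.first_year_treatment_costs[label]
        )
    for i in range(3):
        laws[f"state_costs_direct.{i}"] = cost_law(params.state_costs_direct[i])
        laws[f"state_costs_productivity.{i}"] = cost_law(
            params.state_costs_productivity[i]
        )
    return ParameterDistributions(base=params, laws=laws)
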