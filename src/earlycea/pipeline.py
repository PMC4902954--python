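"""Run orchestration and report writers.

``run_pipeline`` executes the full chain - strategy algebra, year-1 tree,
state-transition model, economic comparison and (optionally) PSA/OWSA -
for every configured strategy and writes CSV reports: a reclassification
table, a comparison table (one row per strategy with confusion counts,
costs, QALYs, increments, ICER and headroom), PSA/CEAC/tornado tables and
a JSON run manifest.  Every output embeds the parameter hash, so any
change of inputs is visible in the artefacts; outputs for a fixed config
and seed are byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CANDIDATE_TESTS, derive_reference_cohort
from .config import RunConfig
from .economics import compare_strategies, run_strategy
from .parameters import ModelParameters, default_parameters, load_parameters, psa_distributions
from .strategy import (
    StrategyMode,
    StrategySpec,
    reclassify_group,
    resolve_strategy_accuracy,
)
from .uncertainty import ceac, ce_plane_summary, run_owsa, run_psa

__all__ = ["run_pipeline", "reclassification_table", "comparison_table"]

logger = logging.getLogger("earlycea")


def _load_params(config: RunConfig) -> ModelParameters:
    if config.params_file is not None:
        params = load_parameters(config.params_file)
        params.cohort = derive_reference_cohort()
    else:
        params = default_parameters()
    if config.overrides:
        params = params.replace(**config.overrides)
    return params


def reclassification_table(params: ModelParameters) -> pd.DataFrame:
    """Reclassification of the criteria strata under each candidate test,
    with the combined accuracies of both add-on positionings."""
    cohort = params.cohort
    rows = []
    for name, test in CANDIDATE_TESTS.items():
        acc_all = resolve_strategy_accuracy(
            StrategySpec(StrategyMode.ADD_ON_ALL, test), params.base_criteria, cohort
        )
        acc_int = resolve_strategy_accuracy(
            StrategySpec(StrategyMode.ADD_ON_INTERMEDIATE, test),
            params.base_criteria,
            cohort,
        )
        for group, retested_all, retested_int in (
            (cohort.high, False, False),
            (cohort.intermediate, True, True),
            (cohort.low, True, False),
        ):
            to_high_all, to_low_all = (
                reclassify_group(group, test.accuracy)
                if retested_all
                else ((group.size, 0) if group.label == "high" else (0, group.size))
            )
            to_high_int, to_low_int = (
                reclassify_group(group, test.accuracy)
                if retested_int
                else ((group.size, 0) if group.label == "high" else (0, group.size))
            )
            rows.append(
                {
                    "test": name,
                    "risk_group": group.label,
                    "n": group.size,
                    "add_on_all_to_high": to_high_all,
                    "add_on_all_to_low": to_low_all,
                    "add_on_intermediate_to_high": to_high_int,
                    "add_on_intermediate_to_low": to_low_int,
                    "combined_se_all": acc_all.sensitivity,
                    "combined_sp_all": acc_all.specificity,
                    "combined_se_intermediate": acc_int.sensitivity,
                    "combined_sp_intermediate": acc_int.specificity,
                }
            )
    return pd.DataFrame(rows)


def comparison_table(
    config: RunConfig, params: ModelParameters
) -> pd.DataFrame:
    """One comparison row per configured strategy versus the current one."""
    cohort = params.cohort
    current = StrategySpec(StrategyMode.CURRENT)
    run_cur = run_strategy(cohort, current, params, config.seed, mode=config.mode)
    rows = [
        {
            "strategy": "current",
            "sensitivity": params.base_criteria.sensitivity,
            "specificity": params.base_criteria.specificity,
            "test_cost": params.current_workup_cost,
            "tp": run_cur.first_year.counts.tp,
            "fp": run_cur.first_year.counts.fp,
            "tn": run_cur.first_year.counts.tn,
            "fn": run_cur.first_year.counts.fn,
            "mean_cost": run_cur.mean_cost,
            "mean_qaly": run_cur.mean_qaly,
            "delta_cost": 0.0,
            "delta_qaly": 0.0,
            "icer": "",
            "headroom": "",
        }
    ]
    for sc in config.strategies:
        if sc.mode == "current":
            continue
        spec = sc.to_spec()
        run_new = run_strategy(cohort, spec, params, config.seed, mode=config.mode)
        cmp = compare_strategies(run_cur, run_new, params)
        rows.append(
            {
                "strategy": cmp.strategy_label,
                "sensitivity": spec.test.accuracy.sensitivity,
                "specificity": spec.test.accuracy.specificity,
                "test_cost": spec.test.unit_cost,
                "tp": run_new.first_year.counts.tp,
                "fp": run_new.first_year.counts.fp,
                "tn": run_new.first_year.counts.tn,
                "fn": run_new.first_year.counts.fn,
                "mean_cost": cmp.mean_cost,
                "mean_qaly": cmp.mean_qaly,
                "delta_cost": cmp.delta_cost,
                "delta_qaly": cmp.delta_qaly,
                "icer": cmp.icer if cmp.icer is not None else "undefined",
                "headroom": cmp.headroom if cmp.headroom is not None else "",
            }
        )
    return pd.DataFrame(rows)


def _display_variant(df: pd.DataFrame) -> pd.DataFrame:
    """Display rounding mirroring the published table layout: whole euros,
    QALYs to 3 decimals, ICER to whole euros per QALY."""
    def _round_euro(v):
        if isinstance(v, (int, float)) and v == v:  # numeric, not NaN
            return round(v)
        return v

    out = df.copy()
    for col in ("mean_cost", "delta_cost", "headroom", "test_cost", "icer"):
        out[col] = [_round_euro(v) for v in out[col]]
    out["mean_qaly"] = out["mean_qaly"].round(3)
    out["delta_qaly"] = out["delta_qaly"].round(3)
    return out


def _write_csv(df: pd.DataFrame, path: Path, param_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# parameter_hash={param_hash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig, psa: bool = False, owsa: bool = False) -> Dict[str, Path]:
    """Execute the configured run end to end and write all reports.

    Returns a mapping of artefact name to path.  On failure, files already
    written for this run are removed so no partial bundle survives.
    """
    config.validate()
    params = _load_params(config)
    param_hash = params.param_hash()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    artefacts: Dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out_dir / f"{name}.csv"
        _write_csv(df, path, param_hash)
        written.append(path)
        artefacts[name] = path

    try:
        logger.info("pipeline start: seed=%d hash=%s", config.seed, param_hash)
        emit("reclassification", reclassification_table(params))
        comparison = comparison_table(config, params)
        emit("comparison", comparison)
        emit("comparison_display", _display_variant(comparison))

        if psa or owsa:
            dists = psa_distributions(params)
            for sc in config.strategies:
                if sc.mode == "current":
                    continue
                spec = sc.to_spec()
                tag = spec.label.replace(":", "_")
                if psa:
                    logger.info("PSA for %s (%d draws)", spec.label, config.n_sims)
                    draws = run_psa(
                        params.cohort, spec, params, dists, config.n_sims,
                        config.seed, mode=config.mode,
                    )
                    emit(
                        f"psa_{tag}",
                        pd.DataFrame(
                            {"delta_cost": draws.delta_cost, "delta_qaly": draws.delta_qaly}
                        ),
                    )
                    quad = ce_plane_summary(draws)
                    grid = np.arange(0.0, 100001.0, 2500.0)
                    emit(
                        f"ceac_{tag}",
                        pd.DataFrame({"wtp": grid, "p_cost_effective": ceac(draws, grid)}),
                    )
                    emit(f"ce_plane_{tag}", pd.DataFrame([quad]))
                if owsa:
                    logger.info("OWSA for %s", spec.label)
                    entries = run_owsa(params.cohort, spec, params, config.seed, mode=config.mode)
                    emit(
                        f"tornado_{tag}",
                        pd.DataFrame(
                            [
                                {
                                    "parameter": e.parameter,
                                    "low": e.low,
                                    "high": e.high,
                                    "icer_low": e.icer_low,
                                    "icer_high": e.icer_high,
                                    "icer_base": e.icer_base,
                                    "span": e.span,
                                }
                                for e in entries
                            ]
                        ),
                    )

        manifest = {
            "seed": config.seed,
            "n_sims": config.n_sims,
            "mode": config.mode,
            "parameter_hash": param_hash,
            "version": __version__,
            "strategies": [s.name for s in config.strategies],
            "artefacts": {k: v.name for k, v in artefacts.items()},
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(manifest_path)
        artefacts["manifest"] = manifest_path
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return artefacts
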