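"""Run configuration: schema, validation and strategy construction."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import yaml

from .strategy import DiagnosticTest, StrategyMode, StrategySpec, TestAccuracy

__all__ = ["StrategyConfig", "RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Configuration schema violation; the message names the field path."""


@dataclass(frozen=True)
class StrategyConfig:
    name: str
    mode: str
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    unit_cost: Optional[float] = None

    def to_spec(self) -> StrategySpec:
        if self.mode == "current":
            return StrategySpec(StrategyMode.CURRENT)
        test = DiagnosticTest(
            self.name,
            TestAccuracy(self.sensitivity, self.specificity),
            self.unit_cost,
        )
        return StrategySpec(StrategyMode(self.mode), test)


@dataclass
class RunConfig:
    """Validated run configuration for the pipeline and CLI."""

    seed: int
    out_dir: Path
    strategies: List[StrategyConfig]
    params_file: Optional[Path] = None
    n_sims: int = 1000
    mode: str = "expectation"  # expectation | patient
    overrides: Dict[str, Any] = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise ConfigError("seed: must be an integer")
        if self.n_sims < 1:
            raise ConfigError("n_sims: must be >= 1")
        if self.mode not in ("expectation", "patient"):
            raise ConfigError(f"mode: unknown value {self.mode!r}")
        if self.params_file is not None and not Path(self.params_file).exists():
            raise ConfigError(f"params_file: no such file {self.params_file}")
        if not self.strategies:
            raise ConfigError("strategies: at least one strategy is required")
        valid_modes = {m.value for m in StrategyMode}
        for i, s in enumerate(self.strategies):
            where = f"strategies[{i}]"
            if s.mode not in valid_modes:
                raise ConfigError(f"{where}.mode: unknown value {s.mode!r}")
            if s.mode != "current":
                for fname in ("sensitivity", "specificity", "unit_cost"):
                    v = getattr(self, "strategies")[i].__getattribute__(fname)
                    if v is None:
                        raise ConfigError(f"{where}.{fname}: required for mode {s.mode!r}")
                if not (0.0 <= s.sensitivity <= 1.0):
                    raise ConfigError(f"{where}.sensitivity: must be in [0, 1]")
                if not (0.0 <= s.specificity <= 1.0):
                    raise ConfigError(f"{where}.specificity: must be in [0, 1]")
                if s.unit_cost < 0:
                    raise ConfigError(f"{where}.unit_cost: must be >= 0")
        return self


def load_config(path) -> RunConfig:
    """Load a YAML/JSON run configuration and validate its schema."""
    with open(path, "r") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    try:
        strategies = [
            StrategyConfig(**entry) for entry in doc.get("strategies", [])
        ]
    except TypeError as exc:
        raise ConfigError(f"strategies: {exc}") from exc
    cfg = RunConfig(
        seed=doc.get("seed", 0),
        out_dir=Path(doc.get("out_dir", "earlycea_out")),
        strategies=strategies,
        params_file=Path(doc["params_file"]) if doc.get("params_file") else None,
        n_sims=doc.get("n_sims", 1000),
        mode=doc.get("mode", "expectation"),
        overrides=doc.get("overrides", {}) or {},
    )
    return cfg.validate()
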