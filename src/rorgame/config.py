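"""Validated run configuration for the command-line interface.

Defaults equal the study constants: tau = 1.54 (Cognitive Hierarchy), k = 5
(naive sampler), K = 9 / omega = 0.5 / epsilon = 0.4 (SAW), 60 trials,
4-player groups, 5% timeout rate.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional, Union

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    condition: str = "basic"
    model: str = "naive_sampler"
    k: int = 5
    K: int = 9
    omega: float = 0.5
    epsilon: float = 0.4
    tau: float = 1.54
    max_level: int = 12
    n_groups: int = 2000
    n_trials: int = 60
    n_players: int = 4
    seed: int = 0
    timeout_rate: float = 0.05
    out: Optional[str] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        from .game import CONDITION_NAMES

        if self.condition not in CONDITION_NAMES:
            raise ValueError(
                f"condition must be one of {CONDITION_NAMES}, got {self.condition!r}"
            )
        if self.model not in ("naive_sampler", "saw"):
            raise ValueError("model must be 'naive_sampler' or 'saw'")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError(f"omega must lie in [0, 1], got {self.omega}")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must lie in [0, 1], got {self.epsilon}")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.max_level < 1:
            raise ValueError("max_level must be >= 1")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.n_players != 4:
            raise ValueError("n_players is fixed at 4 by the game design")
        if not 0.0 <= self.timeout_rate < 1.0:
            raise ValueError(f"timeout_rate must lie in [0, 1), got {self.timeout_rate}")
        if self.log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValueError("log_level must be DEBUG/INFO/WARNING/ERROR")

    def model_config(self) -> dict:
        if self.model == "naive_sampler":
            return {"model": "naive_sampler", "k": self.k}
        return {
            "model": "saw",
            "K": self.K,
            "omega": self.omega,
            "epsilon": self.epsilon,
        }

    def to_dict(self) -> dict:
        return asdict(self)

    def write(self, path: Union[str, Path]) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_config(
    path: Optional[Union[str, Path]] = None, **overrides
) -> RunConfig:
    """Load a YAML/JSON config file, apply flag overrides, validate.

    Unknown keys are rejected; ``None``-valued overrides are ignored so CLI
    flags left at their default do not mask file values.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = (
            json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        )
        if loaded:
            data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
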