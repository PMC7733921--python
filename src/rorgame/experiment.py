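"""Synthetic participant-level datasets with the structure of the experiment.

Generates choice data mimicking the study design — groups of four, 60 trials,
full obtained/forgone feedback, occasional timeouts whose auto-submitted
choice repeats the previous one (Responsible on trial 1) with a 2-point
penalty, and the monetary payment rule ($1 show-up, $2 for making more than
40 of the 60 choices on time, and up to $1 performance bonus awarded with
probability linear in accumulated points). Agents behave per a sampler model
(default naive sampler, k = 5). The human data of the study are not public,
so these datasets exist to exercise the analysis pipeline, not to replicate
observed rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .agents import Model, NaiveSampler, model_from_config
from .game import ConditionSpec, build_condition
from .simulate import DEFAULT_N_TRIALS, _run_group, group_rngs

__all__ = [
    "ParticipantProfile",
    "PaymentRule",
    "TIMEOUT_PENALTY",
    "generate_experiment",
    "compute_payment",
    "attainable_points_range",
    "payment_rule_for",
    "write_dataset",
    "read_dataset",
]

TIMEOUT_PENALTY = -2.0
DEFAULT_TIMEOUT_RATE = 0.05

# Response time limits (seconds) are design metadata only; no reaction-time
# process is modeled.
TIME_LIMIT_S = 12.0
TIME_LIMIT_FIRST_TRIALS_S = 20.0

DATASET_COLUMNS = [
    "condition",
    "group_id",
    "participant_id",
    "trial",
    "choice",
    "obtained",
    "forgone",
    "timed_out",
    "penalty",
]


@dataclass(frozen=True)
class ParticipantProfile:
    """Behavioral model plus per-trial timeout probability."""

    model: Model = field(default_factory=NaiveSampler)
    timeout_rate: float = DEFAULT_TIMEOUT_RATE

    def __post_init__(self) -> None:
        if not 0.0 <= self.timeout_rate < 1.0:
            raise ValueError("timeout_rate must lie in [0, 1)")


@dataclass(frozen=True)
class PaymentRule:
    """Monetary payment: show-up fee, on-time bonus, performance bonus.

    The performance bonus is a Bernoulli $1 with success probability linear
    in total points between the condition's minimal and maximal attainable
    totals (clipped to [0, 1]); the mapping from points to probability is a
    documented stand-in, the original being unpublished.
    """

    show_up: float = 1.0
    on_time_bonus: float = 2.0
    on_time_threshold: int = 40  # strictly more than this many on-time choices
    performance_bonus: float = 1.0
    min_points: float = 0.0
    max_points: float = 1.0

    def bonus_probability(self, total_points: float) -> float:
        if self.max_points <= self.min_points:
            return 0.0
        frac = (total_points - self.min_points) / (self.max_points - self.min_points)
        return float(np.clip(frac, 0.0, 1.0))


def attainable_points_range(
    spec: ConditionSpec, n_trials: int = DEFAULT_N_TRIALS
) -> tuple[float, float]:
    """Minimal and maximal total points attainable in a session.

    The minimum assumes the worst lottery outcome plus the timeout penalty on
    every trial; the maximum assumes the best outcome with no timeouts.
    """
    reckless = spec.reckless_lottery._payoffs
    responsible = [0.0] if spec.externality_removed else [0.0, *spec.exposure._payoffs]
    worst = min(reckless.min(), min(responsible)) + TIMEOUT_PENALTY
    best = max(reckless.max(), max(responsible))
    return n_trials * worst, n_trials * best


def payment_rule_for(
    spec: ConditionSpec, n_trials: int = DEFAULT_N_TRIALS
) -> PaymentRule:
    """Payment rule with bonus scaling anchored to a condition's point range."""
    lo, hi = attainable_points_range(spec, n_trials)
    return PaymentRule(min_points=lo, max_points=hi)


def compute_payment(
    total_points: float,
    n_on_time: int,
    rule: PaymentRule,
    rng: np.random.Generator,
    n_trials: int = DEFAULT_N_TRIALS,
) -> float:
    """Dollars earned: show-up + conditional on-time bonus + Bernoulli bonus.

    The on-time bonus requires strictly more than ``rule.on_time_threshold``
    on-time choices (40 of 60 in the original design).
    """
    if not 0 <= n_on_time <= n_trials:
        raise ValueError(f"n_on_time must lie in [0, {n_trials}]")
    pay = rule.show_up
    if n_on_time > rule.on_time_threshold:
        pay += rule.on_time_bonus
    if rng.random() < rule.bonus_probability(total_points):
        pay += rule.performance_bonus
    return pay


def generate_experiment(
    spec: Union[ConditionSpec, str],
    n_groups: int,
    profile: ParticipantProfile = ParticipantProfile(),
    seed: int = 0,
    n_trials: int = DEFAULT_N_TRIALS,
) -> pd.DataFrame:
    """Generate a tidy per-trial choice dataset for one condition.

    Returns one row per (group, participant, trial) with choice, obtained and
    forgone payoffs, timeout flag and penalty. Participant ids are globally
    unique (``group_id * 4 + player``). Timeout penalties affect earnings
    only; they never enter agents' experienced option payoffs.
    """
    if isinstance(spec, str):
        spec = build_condition(spec)
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    frames = []
    for g in range(n_groups):
        game_rng, timeout_rng = group_rngs(seed, g)
        trace = _run_group(
            model=profile.model,
            spec=spec,
            n_trials=n_trials,
            game_rng=game_rng,
            timeout_rate=profile.timeout_rate,
            timeout_rng=timeout_rng,
            seed=seed,
        )
        df = trace.to_dataframe(group_id=g)
        df["participant_id"] = g * trace.n_players + df.pop("player")
        df["timed_out"] = trace.timed_out.ravel()
        df["penalty"] = np.where(df["timed_out"], TIMEOUT_PENALTY, 0.0)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[DATASET_COLUMNS]


def dataset_manifest(
    spec: Union[ConditionSpec, str],
    n_groups: int,
    profile: ParticipantProfile,
    seed: int,
    n_trials: int = DEFAULT_N_TRIALS,
) -> dict:
    """Sidecar metadata sufficient to regenerate a dataset exactly."""
    if isinstance(spec, str):
        spec = build_condition(spec)
    return {
        "condition": spec.to_dict(),
        "n_groups": n_groups,
        "n_trials": n_trials,
        "seed": seed,
        "model": profile.model.config(),
        "timeout_rate": profile.timeout_rate,
        "time_limit_s": TIME_LIMIT_S,
        "time_limit_first_trials_s": TIME_LIMIT_FIRST_TRIALS_S,
        "payment_rule": payment_rule_for(spec, n_trials).__dict__,
    }


def profile_from_manifest(manifest: dict) -> ParticipantProfile:
    return ParticipantProfile(
        model=model_from_config(manifest["model"]),
        timeout_rate=manifest["timeout_rate"],
    )


def write_dataset(
    df: pd.DataFrame, path: Union[str, Path], manifest: Optional[dict] = None
) -> None:
    """Write a choice dataset as CSV, with an optional sidecar JSON manifest."""
    path = Path(path)
    df.to_csv(path, index=False)
    if manifest is not None:
        path.with_suffix(".manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )


def read_dataset(path: Union[str, Path]) -> pd.DataFrame:
    """Read a choice dataset CSV back with the canonical schema and dtypes."""
    df = pd.read_csv(
        path,
        dtype={
            "condition": str,
            "group_id": np.int64,
            "participant_id": np.int64,
            "trial": np.int64,
            "choice": str,
            "obtained": float,
            "forgone": float,
            "timed_out": bool,
            "penalty": float,
        },
    )
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dataset missing columns: {sorted(missing)}")
    return df[DATASET_COLUMNS]
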