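"""Analytic Cognitive Hierarchy predictions for the game variants.

Reasoning levels follow a Poisson(tau) distribution truncated at a maximum
level and renormalized. Level-0 players randomize uniformly; each level
k >= 1 best-responds in expected value to the renormalized distribution of
strictly lower levels, treating its three partners as independently
responsible with the belief probability implied by that distribution. The
population responsible rate aggregates the per-level choice probabilities
with the Poisson weights. With the standard parameter tau = 1.54 this
predicts that removing the social externality (alert) is as effective as
certain gentle enforcement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .game import Choice, ConditionSpec, lottery_ev

__all__ = [
    "CHParams",
    "LevelProfile",
    "poisson_weights",
    "ev_given_belief",
    "ch_responsible_rate",
    "ch_level_profile",
]

DEFAULT_TAU = 1.54
DEFAULT_MAX_LEVEL = 12


@dataclass(frozen=True)
class CHParams:
    """Poisson mean tau (default 1.54) and truncation level (default 12)."""

    tau: float = DEFAULT_TAU
    max_level: int = DEFAULT_MAX_LEVEL

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not (isinstance(self.max_level, (int, np.integer)) and self.max_level >= 1):
            raise ValueError("max_level must be an integer >= 1")


@dataclass(frozen=True)
class LevelProfile:
    """Normalized level weights and per-level P(RESPONSIBLE)."""

    weights: np.ndarray
    responsible_prob_by_level: np.ndarray

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("level weights must sum to 1")
        if self.responsible_prob_by_level[0] != 0.5:
            raise ValueError("level-0 must randomize uniformly")

    @property
    def responsible_rate(self) -> float:
        return float(self.weights @ self.responsible_prob_by_level)


def poisson_weights(tau: float, max_level: int = DEFAULT_MAX_LEVEL) -> np.ndarray:
    """Poisson(tau) pmf at levels 0..max_level, renormalized to sum 1."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    levels = np.arange(max_level + 1)
    pmf = stats.poisson.pmf(levels, tau) if tau > 0 else (levels == 0).astype(float)
    return pmf / pmf.sum()


def ev_given_belief(
    choice: Choice, p_responsible_other: float, spec: ConditionSpec
) -> float:
    """Expected payoff of a choice, partners independently responsible with
    probability ``p_responsible_other``.

    Reckless pays EV(base) + EV(fee) regardless of others. Responsible pays 0
    when the externality is removed or all three partners are responsible,
    else the exposure EV.
    """
    if not 0.0 <= p_responsible_other <= 1.0:
        raise ValueError("belief probability must lie in [0, 1]")
    if choice is Choice.RECKLESS:
        ev = lottery_ev(spec.reckless_base)
        if spec.fee is not None:
            ev += lottery_ev(spec.fee)
        return ev
    if spec.externality_removed:
        return 0.0
    p_all = p_responsible_other**3
    return (1.0 - p_all) * lottery_ev(spec.exposure)


def ch_level_profile(spec: ConditionSpec, params: CHParams = CHParams()) -> LevelProfile:
    """Per-level responsible probabilities under iterated best response.

    Level k best-responds (strict EV comparison, ties toward RESPONSIBLE) to
    the renormalized distribution of levels 0..k-1. Never-binding at the
    printed payoff constants, the tie rule is still defined.
    """
    weights = poisson_weights(params.tau, params.max_level)
    resp_prob = np.empty(params.max_level + 1)
    resp_prob[0] = 0.5
    for k in range(1, params.max_level + 1):
        lower_w = weights[:k]
        belief = float(lower_w @ resp_prob[:k] / lower_w.sum())
        ev_resp = ev_given_belief(Choice.RESPONSIBLE, belief, spec)
        ev_reck = ev_given_belief(Choice.RECKLESS, belief, spec)
        resp_prob[k] = 1.0 if ev_resp >= ev_reck else 0.0
    return LevelProfile(weights, resp_prob)


def ch_responsible_rate(
    spec: ConditionSpec, params: CHParams = CHParams()
) -> tuple[float, float]:
    """Population responsible rate under Cognitive Hierarchy.

    Returns ``(rate, rate rounded to 2 decimals)``, matching the print
    precision of the prediction table.
    """
    rate = ch_level_profile(spec, params).responsible_rate
    return rate, round(rate, 2)
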