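"""Payoff structures and trial resolution for the Reckless-or-Responsible game.

A 4-player repeated game abstracting everyday compliance decisions during a
pandemic. Each trial every player picks Responsible or Reckless. Reckless pays
1 point with probability 0.98 and -60 otherwise (EV = -0.22). Responsible pays
0 when all four players comply; otherwise it is exposed to the same rare -60
loss (the social externality). Policy variants either remove the externality
(a perfectly protecting alert app: Responsible pays 0 with certainty) or tax
the reckless choice with a gentle enforcement fee (-1.2 with certainty, or
-1.2 with probability 0.95 and +24 otherwise).

Payoffs are in points; monetary conversion lives in :mod:`rorgame.experiment`.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import yaml

__all__ = [
    "Choice",
    "Lottery",
    "ConditionSpec",
    "TrialDraws",
    "TrialOutcome",
    "CONDITION_NAMES",
    "N_PLAYERS",
    "build_condition",
    "lottery_ev",
    "draw_trial_events",
    "resolve_trial",
]

N_PLAYERS = 4

CONDITION_NAMES = ("basic", "alert", "always_enforce", "mostly_enforce")


class Choice(enum.Enum):
    """Binary per-trial action. Display labels "A"/"B" are presentation-only."""

    RESPONSIBLE = "RESPONSIBLE"
    RECKLESS = "RECKLESS"

    @property
    def label(self) -> str:
        return "A" if self is Choice.RESPONSIBLE else "B"

    def other(self) -> "Choice":
        return Choice.RECKLESS if self is Choice.RESPONSIBLE else Choice.RESPONSIBLE


@dataclass(frozen=True)
class Lottery:
    """Finite payoff distribution: (payoff, probability) pairs in points.

    Probabilities must be strictly positive and sum to 1 within 1e-12.
    """

    outcomes: tuple[tuple[float, float], ...]

    # derived arrays, cached for the hot path
    _payoffs: np.ndarray = field(init=False, repr=False, compare=False)
    _cumprobs: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        outs = tuple((float(p), float(q)) for p, q in self.outcomes)
        if len(outs) == 0:
            raise ValueError("Lottery needs at least one outcome")
        probs = np.array([q for _, q in outs])
        if np.any(probs <= 0):
            raise ValueError("Lottery probabilities must be strictly positive")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError(f"Lottery probabilities sum to {probs.sum()}, not 1")
        object.__setattr__(self, "outcomes", outs)
        object.__setattr__(self, "_payoffs", np.array([p for p, _ in outs]))
        object.__setattr__(self, "_cumprobs", np.cumsum(probs))

    @property
    def ev(self) -> float:
        """Probability-weighted mean payoff."""
        return float(sum(p * q for p, q in self.outcomes))

    def payoff_at(self, index: Union[int, np.ndarray]) -> Union[float, np.ndarray]:
        """Payoff of the outcome(s) at the given index/indices."""
        return self._payoffs[index]

    def draw_index(self, u: Union[float, np.ndarray]) -> Union[int, np.ndarray]:
        """Map uniform(0,1) draws to outcome indices via the inverse CDF."""
        return np.searchsorted(self._cumprobs, u, side="right")

    def convolve(self, other: "Lottery") -> "Lottery":
        """Distribution of the sum of independent draws from two lotteries."""
        sums: dict[float, float] = {}
        for p1, q1 in self.outcomes:
            for p2, q2 in other.outcomes:
                sums[p1 + p2] = sums.get(p1 + p2, 0.0) + q1 * q2
        return Lottery(tuple(sorted(sums.items())))

    def to_dict(self) -> list[list[float]]:
        return [[p, q] for p, q in self.outcomes]

    @classmethod
    def from_dict(cls, data: Sequence[Sequence[float]]) -> "Lottery":
        return cls(tuple((float(p), float(q)) for p, q in data))


# Table-level payoff constants of the game.
RECKLESS_BASE = Lottery(((1.0, 0.98), (-60.0, 0.02)))
EXPOSURE = Lottery(((0.0, 0.98), (-60.0, 0.02)))
FEE_ALWAYS = Lottery(((-1.2, 1.0),))
FEE_MOSTLY = Lottery(((-1.2, 0.95), (24.0, 0.05)))


@dataclass(frozen=True)
class ConditionSpec:
    """One variant of the Reckless-or-Responsible game.

    ``externality_removed`` is True only for the protecting-alert variant, in
    which Responsible pays 0 for every draw regardless of others' choices.
    ``fee`` applies to every Reckless choice (absent for basic/alert).
    """

    name: str
    reckless_base: Lottery = RECKLESS_BASE
    fee: Optional[Lottery] = None
    exposure: Lottery = EXPOSURE
    externality_removed: bool = False

    @property
    def reckless_lottery(self) -> Lottery:
        """Composed reckless payoff distribution (base plus fee, if any)."""
        if self.fee is None:
            return self.reckless_base
        return self.reckless_base.convolve(self.fee)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "reckless_base": self.reckless_base.to_dict(),
            "fee": None if self.fee is None else self.fee.to_dict(),
            "exposure": self.exposure.to_dict(),
            "externality_removed": self.externality_removed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ConditionSpec":
        return cls(
            name=str(data["name"]),
            reckless_base=Lottery.from_dict(data["reckless_base"]),
            fee=None if data.get("fee") is None else Lottery.from_dict(data["fee"]),
            exposure=Lottery.from_dict(data["exposure"]),
            externality_removed=bool(data["externality_removed"]),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ConditionSpec":
        return cls.from_dict(yaml.safe_load(io.StringIO(text)))


_CONDITIONS = {
    "basic": ConditionSpec("basic"),
    "alert": ConditionSpec("alert", externality_removed=True),
    "always_enforce": ConditionSpec("always_enforce", fee=FEE_ALWAYS),
    "mostly_enforce": ConditionSpec("mostly_enforce", fee=FEE_MOSTLY),
}


def build_condition(name: str) -> ConditionSpec:
    """Return the game variant with the given name.

    Raises ``ValueError`` naming the valid options for an unknown name.
    """
    try:
        return _CONDITIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown condition {name!r}; valid options: "
            + ", ".join(CONDITION_NAMES)
        ) from None


def lottery_ev(lottery: Lottery) -> float:
    """Expected value of a lottery, in points."""
    return lottery.ev


@dataclass(frozen=True)
class TrialDraws:
    """Realized lottery outcomes for one trial, one index triple per player.

    Indices address outcomes of the condition's base, exposure and fee
    lotteries. All events are drawn even when later unused (e.g. exposure
    under alert), so trajectories for a fixed seed do not depend on which
    payoffs are read.
    """

    base_index: np.ndarray
    exposure_index: np.ndarray
    fee_index: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.base_index)
        if not (len(self.exposure_index) == n == len(self.fee_index)):
            raise ValueError("draw arrays must have equal length")

    @classmethod
    def from_flags(
        cls,
        base_rare: Sequence[bool],
        exposure_rare: Sequence[bool],
        fee_index: Optional[Sequence[int]] = None,
    ) -> "TrialDraws":
        """Build draws from rare/common flags (rare = the -60 outcome, index 1)."""
        base = np.asarray(base_rare, dtype=bool).astype(np.intp)
        expo = np.asarray(exposure_rare, dtype=bool).astype(np.intp)
        fee = (
            np.zeros(len(base), dtype=np.intp)
            if fee_index is None
            else np.asarray(fee_index, dtype=np.intp)
        )
        return cls(base, expo, fee)


@dataclass(frozen=True)
class TrialOutcome:
    """Resolved trial: per-player choice, obtained and forgone payoff.

    The forgone payoff is the counterfactual payoff the player would have
    obtained by unilaterally switching choice, with the other players' choices
    and all realized draws held fixed.
    """

    choices: tuple[Choice, ...]
    obtained: np.ndarray
    forgone: np.ndarray


def draw_trial_events(
    spec: ConditionSpec,
    rng: np.random.Generator,
    n_players: int = N_PLAYERS,
) -> TrialDraws:
    """Draw one trial's lottery events, independently per player and option.

    Three uniform vectors are consumed in a fixed order (base, exposure, fee)
    regardless of the condition, so streams stay aligned across conditions.
    """
    u_base = rng.random(n_players)
    u_expo = rng.random(n_players)
    u_fee = rng.random(n_players)
    base_index = spec.reckless_base.draw_index(u_base)
    exposure_index = spec.exposure.draw_index(u_expo)
    if spec.fee is None:
        fee_index = np.zeros(n_players, dtype=np.intp)
    else:
        fee_index = spec.fee.draw_index(u_fee)
    return TrialDraws(base_index, exposure_index, fee_index)


def resolve_trial(
    choices: Sequence[Choice],
    draws: TrialDraws,
    spec: ConditionSpec,
) -> TrialOutcome:
    """Resolve one trial for a full group.

    Reckless pays base + fee. Responsible pays 0 when the externality is
    removed or when no *other* player is reckless (a sole reckless player's
    forgone responsible payoff is 0, since switching makes everyone
    responsible); otherwise it pays the player's realized exposure draw.
    """
    choices = tuple(choices)
    if len(choices) != N_PLAYERS:
        raise ValueError(f"expected {N_PLAYERS} choices, got {len(choices)}")
    if len(draws.base_index) != N_PLAYERS:
        raise ValueError("draws do not cover the full group")

    base = spec.reckless_base.payoff_at(draws.base_index)
    exposure = spec.exposure.payoff_at(draws.exposure_index)
    if spec.fee is None:
        reckless_pay = base
    else:
        reckless_pay = base + spec.fee.payoff_at(draws.fee_index)

    n_reckless = sum(c is Choice.RECKLESS for c in choices)
    obtained = np.empty(N_PLAYERS)
    forgone = np.empty(N_PLAYERS)
    for i, c in enumerate(choices):
        is_reckless = c is Choice.RECKLESS
        others_reckless = n_reckless - is_reckless
        if spec.externality_removed or others_reckless == 0:
            responsible_pay = 0.0
        else:
            responsible_pay = float(exposure[i])
        if is_reckless:
            obtained[i] = reckless_pay[i]
            forgone[i] = responsible_pay
        else:
            obtained[i] = responsible_pay
            forgone[i] = reckless_pay[i]
    return TrialOutcome(choices, obtained, forgone)
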