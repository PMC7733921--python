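"""Experience-based choice rules: the naive sampler and SAW.

Both models operate on a per-agent history of full feedback — every past
trial contributes the realized payoff of *both* options (obtained and
forgone). The naive sampler draws a small random sample of past trials (with
replacement, paired across options) and picks the option with the better
sample mean; it embodies reliance on small samples and hence underweighting
of rare events. SAW (sampling and weighting) generalizes it with an
epsilon-mixture of uniform choice noise and an omega-weighted blend of the
grand mean over the full history with the paired sample mean.

``choice_probability_oracle`` gives the exact choice probability by
enumerating sample compositions over the distinct experience records, and is
used as the independent reference for Monte-Carlo behavior of the samplers.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from .game import Choice

__all__ = [
    "ExperienceRecord",
    "AgentHistory",
    "NaiveSamplerParams",
    "SAWParams",
    "NaiveSampler",
    "SAW",
    "naive_sampler_choose",
    "saw_choose",
    "choice_probability_oracle",
    "model_from_config",
]


@dataclass(frozen=True)
class ExperienceRecord:
    """One trial's joint feedback: payoff of each option, in points."""

    trial_index: int
    payoff_responsible: float
    payoff_reckless: float


class AgentHistory:
    """Append-only ordered record of both options' realized payoffs.

    Backed by growable numpy arrays so sampler models can index cheaply.
    Trial indices run consecutively from 1.
    """

    __slots__ = ("_responsible", "_reckless", "_n")

    def __init__(self, capacity: int = 64) -> None:
        self._responsible = np.empty(capacity)
        self._reckless = np.empty(capacity)
        self._n = 0

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, float]]) -> "AgentHistory":
        """Build a history from (payoff_responsible, payoff_reckless) pairs."""
        hist = cls()
        for resp, reck in pairs:
            hist.append(resp, reck)
        return hist

    def append(self, payoff_responsible: float, payoff_reckless: float) -> None:
        if self._n == len(self._responsible):
            self._responsible = np.concatenate([self._responsible, np.empty(self._n)])
            self._reckless = np.concatenate([self._reckless, np.empty(self._n)])
        self._responsible[self._n] = payoff_responsible
        self._reckless[self._n] = payoff_reckless
        self._n += 1

    def __len__(self) -> int:
        return self._n

    @property
    def responsible(self) -> np.ndarray:
        """Responsible-option payoffs, one per past trial (read-only view)."""
        return self._responsible[: self._n]

    @property
    def reckless(self) -> np.ndarray:
        return self._reckless[: self._n]

    def records(self) -> list[ExperienceRecord]:
        return [
            ExperienceRecord(i + 1, float(r), float(x))
            for i, (r, x) in enumerate(zip(self.responsible, self.reckless))
        ]


@dataclass(frozen=True)
class NaiveSamplerParams:
    """Sample size of the naive sampler (k past trials, default 5)."""

    k: int = 5

    def __post_init__(self) -> None:
        if not (isinstance(self.k, (int, np.integer)) and self.k >= 1):
            raise ValueError("k must be an integer >= 1")


@dataclass(frozen=True)
class SAWParams:
    """SAW parameters: sample size K, grand-mean weight omega, noise epsilon."""

    K: int = 9
    omega: float = 0.5
    epsilon: float = 0.4

    def __post_init__(self) -> None:
        if not (isinstance(self.K, (int, np.integer)) and self.K >= 1):
            raise ValueError("K must be an integer >= 1")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must lie in [0, 1]")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")


def _coin(rng: np.random.Generator) -> Choice:
    return Choice.RESPONSIBLE if rng.random() < 0.5 else Choice.RECKLESS


class NaiveSampler:
    """Pick the option with the better mean payoff in a random sample of k
    past trials (with replacement, paired across options); Responsible on the
    first trial; exact ties broken uniformly at random."""

    name = "naive_sampler"

    def __init__(self, params: NaiveSamplerParams = NaiveSamplerParams()) -> None:
        self.params = params

    def choose(self, history: AgentHistory, rng: np.random.Generator) -> Choice:
        n = len(history)
        if n == 0:
            return Choice.RESPONSIBLE
        idx = rng.integers(0, n, self.params.k)
        diff = history.responsible[idx].sum() - history.reckless[idx].sum()
        if diff > 0:
            return Choice.RESPONSIBLE
        if diff < 0:
            return Choice.RECKLESS
        return _coin(rng)

    def config(self) -> dict:
        return {"model": self.name, "k": self.params.k}


class SAW:
    """Sampling-and-weighting rule: with probability epsilon choose uniformly
    at random; otherwise score each option as
    omega * (grand mean over the full history) + (1 - omega) * (paired mean
    over K sampled trials) and pick the argmax. Responsible on the first
    trial; ties broken uniformly at random."""

    name = "saw"

    def __init__(self, params: SAWParams = SAWParams()) -> None:
        self.params = params

    def choose(self, history: AgentHistory, rng: np.random.Generator) -> Choice:
        n = len(history)
        if n == 0:
            return Choice.RESPONSIBLE
        p = self.params
        if rng.random() < p.epsilon:
            return _coin(rng)
        idx = rng.integers(0, n, p.K)
        resp = history.responsible
        reck = history.reckless
        score_resp = p.omega * resp.mean() + (1 - p.omega) * resp[idx].mean()
        score_reck = p.omega * reck.mean() + (1 - p.omega) * reck[idx].mean()
        if score_resp > score_reck:
            return Choice.RESPONSIBLE
        if score_resp < score_reck:
            return Choice.RECKLESS
        return _coin(rng)

    def config(self) -> dict:
        return {
            "model": self.name,
            "K": self.params.K,
            "omega": self.params.omega,
            "epsilon": self.params.epsilon,
        }


Model = Union[NaiveSampler, SAW]


def naive_sampler_choose(
    history: AgentHistory,
    params: NaiveSamplerParams = NaiveSamplerParams(),
    rng: np.random.Generator | None = None,
) -> Choice:
    """Functional form of :class:`NaiveSampler`.choose."""
    return NaiveSampler(params).choose(history, rng or np.random.default_rng())


def saw_choose(
    history: AgentHistory,
    params: SAWParams = SAWParams(),
    rng: np.random.Generator | None = None,
) -> Choice:
    """Functional form of :class:`SAW`.choose."""
    return SAW(params).choose(history, rng or np.random.default_rng())


_MAX_ORACLE_COMPOSITIONS = 200_000


def _sample_branch_probability(
    history: AgentHistory, sample_size: int, omega: float
) -> float:
    # Enumerate samples by composition over *distinct* (responsible, reckless)
    # record pairs with multinomial weights — identical to enumerating all
    # n^sample_size index tuples, but feasible for long histories with few
    # distinct rows.
    resp = history.responsible
    reck = history.reckless
    n = len(resp)
    pairs: dict[tuple[float, float], int] = {}
    for r, x in zip(resp, reck):
        pairs[(float(r), float(x))] = pairs.get((float(r), float(x)), 0) + 1
    values = list(pairs.keys())
    counts = list(pairs.values())
    d = len(values)
    n_comp = math.comb(sample_size + d - 1, d - 1)
    if n_comp > _MAX_ORACLE_COMPOSITIONS:
        raise ValueError(
            f"history has {d} distinct records; enumerating {n_comp} sample "
            "compositions is infeasible"
        )
    grand_resp = float(resp.mean())
    grand_reck = float(reck.mean())
    log_probs = [math.log(m / n) for m in counts]

    p_responsible = 0.0
    total_weight = 0.0
    # compositions of sample_size into d nonneg parts via stars and bars
    for bars in itertools.combinations(range(sample_size + d - 1), d - 1):
        prev = -1
        comp = []
        for b in bars:
            comp.append(b - prev - 1)
            prev = b
        comp.append(sample_size + d - 1 - prev - 1)
        log_w = math.lgamma(sample_size + 1)
        s_resp = 0.0
        s_reck = 0.0
        for c, (r, x), lp in zip(comp, values, log_probs):
            log_w += c * lp - math.lgamma(c + 1)
            s_resp += c * r
            s_reck += c * x
        w = math.exp(log_w)
        total_weight += w
        score_resp = omega * grand_resp + (1 - omega) * s_resp / sample_size
        score_reck = omega * grand_reck + (1 - omega) * s_reck / sample_size
        if score_resp > score_reck:
            p_responsible += w
        elif score_resp == score_reck:
            p_responsible += 0.5 * w
    # weights sum to 1 only up to rounding; normalize so that degenerate
    # cases (all compositions agree) come out exactly 0, 0.5 or 1
    return p_responsible / total_weight


def choice_probability_oracle(history: AgentHistory, model: Model) -> float:
    """Exact P(RESPONSIBLE) of a sampler model on a history, by enumeration.

    Enumerates every sample composition (with multinomial weights over
    distinct records) and both tie branches. Raises for histories whose
    enumeration is infeasible.
    """
    if len(history) == 0:
        return 1.0
    if isinstance(model, NaiveSampler):
        return _sample_branch_probability(history, model.params.k, omega=0.0)
    if isinstance(model, SAW):
        p = model.params
        branch = _sample_branch_probability(history, p.K, omega=p.omega)
        return p.epsilon * 0.5 + (1 - p.epsilon) * branch
    raise TypeError(f"unknown model type: {type(model)!r}")


def model_from_config(config: dict) -> Model:
    """Build a sampler model from a config mapping.

    Accepts ``{"model": "naive_sampler", "k": 5}`` or
    ``{"model": "saw", "K": 9, "omega": 0.5, "epsilon": 0.4}``.
    """
    cfg = dict(config)
    name = cfg.pop("model")
    if name == "naive_sampler":
        return NaiveSampler(NaiveSamplerParams(**cfg))
    if name == "saw":
        return SAW(SAWParams(**cfg))
    raise ValueError(f"unknown model {name!r}; valid options: naive_sampler, saw")
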