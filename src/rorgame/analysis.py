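"""Statistical treatment of choice datasets.

Responsible rates at participant / group / condition level (the group is the
unit of analysis: condition means and SDs are computed across group rates),
Welch unequal-variance t-tests with Welch–Satterthwaite degrees of freedom
and confidence intervals in percentage points, learning curves over five
blocks of 12 trials, and first-trial summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .game import N_PLAYERS, Choice

__all__ = [
    "RateTable",
    "WelchResult",
    "BlockCurve",
    "responsible_rates",
    "welch_test",
    "block_rates",
    "first_trial_summary",
    "plot_block_curves",
]


@dataclass(frozen=True)
class RateTable:
    """Responsible rates per participant and group, summarized per condition.

    ``conditions`` holds the across-group mean, SD (ddof=1) and group count.
    """

    participants: pd.DataFrame
    groups: pd.DataFrame
    conditions: pd.DataFrame

    def group_rates(self, condition: str) -> np.ndarray:
        sub = self.groups[self.groups["condition"] == condition]
        if sub.empty:
            raise KeyError(f"no groups for condition {condition!r}")
        return sub["rate"].to_numpy()


def _validate(df: pd.DataFrame) -> None:
    for (cond, gid), sub in df.groupby(["condition", "group_id"]):
        n_part = sub["participant_id"].nunique()
        if n_part != N_PLAYERS:
            raise ValueError(
                f"group {gid} of condition {cond!r} has {n_part} participants, "
                f"expected {N_PLAYERS}"
            )
        counts = sub.groupby("participant_id")["trial"].count()
        if counts.nunique() != 1:
            raise ValueError(
                f"group {gid} of condition {cond!r} has unequal trial counts"
            )


def _rate_table(df: pd.DataFrame) -> RateTable:
    resp = (df["choice"] == Choice.RESPONSIBLE.value).astype(float)
    per_part = (
        df.assign(responsible=resp)
        .groupby(["condition", "group_id", "participant_id"], as_index=False)[
            "responsible"
        ]
        .mean()
        .rename(columns={"responsible": "rate"})
    )
    per_group = (
        per_part.groupby(["condition", "group_id"], as_index=False)["rate"].mean()
    )
    per_cond = per_group.groupby("condition")["rate"].agg(
        mean="mean", sd=lambda x: x.std(ddof=1), n_groups="count"
    ).reset_index()
    return RateTable(per_part, per_group, per_cond)


def responsible_rates(df: pd.DataFrame) -> RateTable:
    """Responsible-choice proportions at all aggregation levels.

    Participant rate = proportion of trials choosing Responsible; group rate
    = mean over its four participants; condition mean/SD across group rates.
    Raises for malformed datasets, naming the offending group.
    """
    _validate(df)
    return _rate_table(df)


@dataclass(frozen=True)
class WelchResult:
    """Welch two-sample test of group-level rates.

    The difference and its confidence interval are reported in percentage
    points as (second sample - first sample).
    """

    t: float
    df: float
    p_value: float
    diff_pp: float
    ci_low_pp: float
    ci_high_pp: float
    confidence: float
    mean_a: float
    mean_b: float
    var_a: float
    var_b: float
    n_a: int
    n_b: int

    def __str__(self) -> str:
        return (
            f"t({self.df:.1f}) = {self.t:.2f}, "
            f"{self.confidence * 100:.0f}% CI [{self.ci_low_pp:.1f}, {self.ci_high_pp:.1f}]"
        )


def welch_test(
    group_rates_a: Sequence[float],
    group_rates_b: Sequence[float],
    confidence: float = 0.95,
) -> WelchResult:
    """Welch unequal-variance t-test of two samples of group rates.

    Degenerate zero-variance identical samples take the t = 0 path with
    pooled degrees of freedom rather than dividing by zero.
    """
    a = np.asarray(group_rates_a, dtype=float)
    b = np.asarray(group_rates_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 groups")
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sa, sb = va / na, vb / nb
    se = np.sqrt(sa + sb)
    if se == 0.0:
        t_stat = 0.0
        dof = float(na + nb - 2)
    else:
        t_stat = (mb - ma) / se
        dof = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t_stat), dof) if se > 0 else 1.0
    crit = stats.t.ppf(0.5 + confidence / 2, dof)
    diff = mb - ma
    return WelchResult(
        t=float(t_stat),
        df=float(dof),
        p_value=float(p),
        diff_pp=float(diff * 100),
        ci_low_pp=float((diff - crit * se) * 100),
        ci_high_pp=float((diff + crit * se) * 100),
        confidence=confidence,
        mean_a=float(ma),
        mean_b=float(mb),
        var_a=float(va),
        var_b=float(vb),
        n_a=na,
        n_b=nb,
    )


@dataclass(frozen=True)
class BlockCurve:
    """Responsible rates over consecutive trial blocks at three levels."""

    participants: pd.DataFrame
    groups: pd.DataFrame
    conditions: pd.DataFrame
    block_size: int


def block_rates(df: pd.DataFrame, block_size: int = 12) -> BlockCurve:
    """Responsible rates in consecutive blocks of ``block_size`` trials.

    The 60-trial session yields five blocks. Raises when the trial count
    does not divide evenly into blocks.
    """
    n_trials = int(df["trial"].max())
    if n_trials % block_size:
        raise ValueError(
            f"{n_trials} trials do not divide into blocks of {block_size}"
        )
    work = df.assign(
        responsible=(df["choice"] == Choice.RESPONSIBLE.value).astype(float),
        block=((df["trial"] - 1) // block_size + 1),
    )
    per_part = (
        work.groupby(
            ["condition", "group_id", "participant_id", "block"], as_index=False
        )["responsible"]
        .mean()
        .rename(columns={"responsible": "rate"})
    )
    per_group = per_part.groupby(
        ["condition", "group_id", "block"], as_index=False
    )["rate"].mean()
    per_cond = per_group.groupby(["condition", "block"], as_index=False)["rate"].mean()
    return BlockCurve(per_part, per_group, per_cond, block_size)


def first_trial_summary(df: pd.DataFrame) -> RateTable:
    """Responsible rates restricted to trial 1 (pre-experience tendencies).

    Group rates take values in {0, 0.25, 0.5, 0.75, 1}; condition mean/SD
    are across groups, as for the overall rates.
    """
    return _rate_table(df[df["trial"] == 1])


def plot_block_curves(curve: BlockCurve, path: Union[str, Path]) -> None:
    """Learning-curve figure: per-group thin lines, condition mean bold."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conditions = sorted(curve.conditions["condition"].unique())
    fig, axes = plt.subplots(
        1, len(conditions), figsize=(3.2 * len(conditions), 3.2), sharey=True, squeeze=False
    )
    for ax, cond in zip(axes[0], conditions):
        for _, sub in curve.groups[curve.groups["condition"] == cond].groupby("group_id"):
            ax.plot(sub["block"], sub["rate"], color="0.7", lw=0.8)
        mean = curve.conditions[curve.conditions["condition"] == cond]
        ax.plot(mean["block"], mean["rate"], color="k", lw=2.5)
        ax.set_title(cond)
        ax.set_xlabel(f"block ({curve.block_size} trials)")
        ax.set_ylim(-0.02, 1.02)
    axes[0][0].set_ylabel("responsible rate")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
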