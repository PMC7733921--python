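"""Rates, Welch tests, block curves and first-trial summaries."""

import re

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rorgame.analysis import (
    block_rates,
    first_trial_summary,
    plot_block_curves,
    responsible_rates,
    welch_test,
)
from rorgame.game import Choice

RESP = Choice.RESPONSIBLE.value
RECK = Choice.RECKLESS.value


def make_dataset(choice_fn, n_groups=2, n_trials=60, condition="basic"):
    """Dataset with choices prescribed by choice_fn(group, participant, trial)."""
    rows = []
    for g in range(n_groups):
        for p in range(4):
            pid = g * 4 + p
            for t in range(1, n_trials + 1):
                rows.append(
                    {
                        "condition": condition,
                        "group_id": g,
                        "participant_id": pid,
                        "trial": t,
                        "choice": choice_fn(g, p, t),
                        "obtained": 0.0,
                        "forgone": 0.0,
                        "timed_out": False,
                        "penalty": 0.0,
                    }
                )
    return pd.DataFrame(rows)


class TestResponsibleRates:
    def test_all_responsible_rates_are_one(self):
        df = make_dataset(lambda g, p, t: RESP)
        table = responsible_rates(df)
        assert (table.participants["rate"] == 1.0).all()
        assert (table.groups["rate"] == 1.0).all()
        assert table.conditions["mean"].iloc[0] == 1.0

    def test_group_rate_is_mean_of_participants(self):
        # participants at rates 0.25, 0.25, 0.75, 0.75 -> group rate 0.50
        quarters = {0: 15, 1: 15, 2: 45, 3: 45}  # responsible trials of 60

        def fn(g, p, t):
            return RESP if t <= quarters[p] else RECK

        table = responsible_rates(make_dataset(fn, n_groups=1))
        assert sorted(table.participants["rate"]) == [0.25, 0.25, 0.75, 0.75]
        assert table.groups["rate"].iloc[0] == 0.5

    def test_condition_summary_matches_hand_computation(self):
        # group 0: rates 1, 1, 0, 0 -> 0.5 ; group 1: 1, 0, 0, 0 -> 0.25
        def fn(g, p, t):
            n_resp = 2 if g == 0 else 1
            return RESP if p < n_resp else RECK

        table = responsible_rates(make_dataset(fn, n_groups=2))
        cond = table.conditions.iloc[0]
        assert cond["mean"] == pytest.approx((0.5 + 0.25) / 2)
        # sample SD of {0.5, 0.25}: |0.5-0.25| / sqrt(2)
        assert cond["sd"] == pytest.approx(0.25 / np.sqrt(2))
        assert cond["n_groups"] == 2

    def test_row_shuffling_is_irrelevant(self):
        def fn(g, p, t):
            return RESP if (g + p + t) % 3 == 0 else RECK

        df = make_dataset(fn, n_groups=3)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        t1 = responsible_rates(df)
        t2 = responsible_rates(shuffled)
        pd.testing.assert_frame_equal(t1.conditions, t2.conditions)

    def test_malformed_group_named_in_error(self):
        df = make_dataset(lambda g, p, t: RESP, n_groups=2)
        df = df[~((df["group_id"] == 1) & (df["participant_id"] == 7))]
        with pytest.raises(ValueError, match="group 1"):
            responsible_rates(df)


class TestWelch:
    def test_identical_samples_give_zero_t(self):
        res = welch_test([0.2, 0.4, 0.6], [0.2, 0.4, 0.6])
        assert res.t == 0.0
        assert res.ci_low_pp < 0 < res.ci_high_pp
        assert res.diff_pp == 0.0

    def test_degenerate_zero_variance_path(self):
        res = welch_test([0.5, 0.5], [0.5, 0.5])
        assert res.t == 0.0 and res.df == 2.0 and res.p_value == 1.0

    def test_hand_computed_example(self):
        # a = {0.10, 0.20}, b = {0.80, 0.90}: means 0.15/0.85, variances
        # 0.005 each; se = sqrt(0.005); t = 0.7/se = 9.8995; df = 2;
        # CI = 70 +- 4.302653 * 7.0711 pp
        res = welch_test([0.10, 0.20], [0.80, 0.90])
        assert res.t == pytest.approx(9.899494936611664)
        assert res.df == pytest.approx(2.0)
        assert res.diff_pp == pytest.approx(70.0)
        assert res.ci_low_pp == pytest.approx(39.5756507770, abs=1e-6)
        assert res.ci_high_pp == pytest.approx(100.4243492230, abs=1e-6)

    def test_formatting_mirrors_reporting_style(self):
        res = welch_test([0.10, 0.20], [0.80, 0.90])
        assert re.fullmatch(
            r"t\(-?\d+\.\d\) = -?\d+\.\d\d, 95% CI \[-?\d+\.\d, -?\d+\.\d\]",
            str(res),
        )

    def test_agrees_with_direct_formulas_and_scipy(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            na, nb = rng.integers(2, 20, 2)
            a = rng.normal(rng.uniform(-1, 1), rng.uniform(0.1, 2), na)
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.1, 2), nb)
            res = welch_test(a, b)
            # direct arithmetic on means and variances
            sa, sb = a.var(ddof=1) / na, b.var(ddof=1) / nb
            t_direct = (b.mean() - a.mean()) / np.sqrt(sa + sb)
            df_direct = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
            assert res.t == pytest.approx(t_direct, abs=1e-10)
            assert res.df == pytest.approx(df_direct, abs=1e-10)
            assert res.df <= na + nb - 2 + 1e-12
            # independent implementation: scipy's unequal-variance test
            t_sp, p_sp = stats.ttest_ind(b, a, equal_var=False)
            assert res.t == pytest.approx(t_sp, abs=1e-10)
            assert res.p_value == pytest.approx(p_sp, abs=1e-10)
            assert res.ci_low_pp <= res.diff_pp <= res.ci_high_pp

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_test([0.5], [0.1, 0.2])


class TestBlockRates:
    def test_sixty_trials_give_five_blocks(self):
        df = make_dataset(lambda g, p, t: RESP)
        curve = block_rates(df)
        assert sorted(curve.conditions["block"]) == [1, 2, 3, 4, 5]

    def test_constant_choices_give_flat_curve(self):
        df = make_dataset(lambda g, p, t: RESP if p == 0 else RECK)
        curve = block_rates(df)
        assert (curve.conditions["rate"] == 0.25).all()

    def test_alternating_choices_give_half_everywhere(self):
        df = make_dataset(lambda g, p, t: RESP if t % 2 else RECK)
        curve = block_rates(df)
        assert (curve.conditions["rate"] == 0.5).all()

    def test_non_divisible_block_size_rejected(self):
        df = make_dataset(lambda g, p, t: RESP)
        with pytest.raises(ValueError):
            block_rates(df, block_size=7)

    def test_block_means_recover_overall_rates(self):
        def fn(g, p, t):
            return RESP if (t * 7 + p * 3 + g) % 5 < 2 else RECK

        df = make_dataset(fn, n_groups=3)
        curve = block_rates(df)
        table = responsible_rates(df)
        # participant curve means equal participant overall rates
        per = curve.participants.groupby("participant_id")["rate"].mean()
        overall = table.participants.set_index("participant_id")["rate"]
        pd.testing.assert_series_equal(per, overall, check_names=False)
        # condition mean over blocks equals condition overall mean
        assert curve.conditions["rate"].mean() == pytest.approx(
            table.conditions["mean"].iloc[0]
        )


class TestFirstTrial:
    def test_all_responsible_first_trial(self):
        df = make_dataset(lambda g, p, t: RESP if t == 1 else RECK)
        table = first_trial_summary(df)
        assert table.conditions["mean"].iloc[0] == 1.0

    def test_single_responsible_gives_quarter(self):
        df = make_dataset(lambda g, p, t: RESP if (t == 1 and p == 0) else RECK)
        table = first_trial_summary(df)
        assert (table.groups["rate"] == 0.25).all()

    def test_twelve_group_fixture_matches_hand_computation(self):
        # groups 0-5 have one responsible starter, groups 6-11 have three
        def fn(g, p, t):
            if t != 1:
                return RECK
            n_resp = 1 if g < 6 else 3
            return RESP if p < n_resp else RECK

        df = make_dataset(fn, n_groups=12)
        table = first_trial_summary(df)
        rates = np.array([0.25] * 6 + [0.75] * 6)
        cond = table.conditions.iloc[0]
        assert cond["mean"] == pytest.approx(rates.mean())
        assert cond["sd"] == pytest.approx(rates.std(ddof=1))


def test_plot_writes_figure(tmp_path):
    df = make_dataset(lambda g, p, t: RESP if t % 2 else RECK, n_groups=2)
    plot_block_curves(block_rates(df), tmp_path / "curves.png")
    assert (tmp_path / "curves.png").stat().st_size > 0
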