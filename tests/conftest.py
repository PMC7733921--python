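import itertools

import numpy as np
import pytest

from rorgame.game import (
    CONDITION_NAMES,
    Choice,
    TrialDraws,
    build_condition,
)

R = Choice.RESPONSIBLE
K = Choice.RECKLESS


@pytest.fixture(params=CONDITION_NAMES)
def condition(request):
    """Each of the four game variants in turn."""
    return build_condition(request.param)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def all_choice_profiles():
    """All 16 choice profiles of a 4-player group."""
    return list(itertools.product((R, K), repeat=4))


def all_draw_combos(spec):
    """Exhaustive per-player rare/common (and fee outcome) draw combinations.

    Yields TrialDraws covering every base-rare pattern x exposure-rare
    pattern, and every fee-outcome pattern when the fee lottery has more
    than one outcome.
    """
    fee_n = 1 if spec.fee is None else len(spec.fee.outcomes)
    fee_patterns = (
        [np.zeros(4, dtype=np.intp)]
        if fee_n == 1
        else [np.array(p, dtype=np.intp) for p in itertools.product(range(fee_n), repeat=4)]
    )
    bool_patterns = [np.array(p, dtype=bool) for p in itertools.product((False, True), repeat=4)]
    for base in bool_patterns:
        for expo in bool_patterns:
            for fee in fee_patterns:
                yield TrialDraws(base.astype(np.intp), expo.astype(np.intp), fee)
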