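# Methods

## The game

`rorgame` simulates a 4-player repeated binary-choice game abstracting
compliance decisions during a pandemic. Each of 60 trials every player picks
**Reckless** or **Responsible**:

- Reckless pays 1 point with probability 0.98 and −60 otherwise
  (EV = −0.22). The rare loss stands for an infection event.
- Responsible pays 0 when all four players are responsible. When at least
  one *other* player is reckless, the responsible player is exposed to the
  same rare loss: 0 with probability 0.98, −60 otherwise. This is the social
  externality.

Four policy variants (`basic`, `alert`, `always_enforce`, `mostly_enforce`):

| variant | change relative to basic | reckless EV |
|---|---|---|
| basic | — | −0.22 |
| alert | externality removed: Responsible pays 0 with certainty | −0.22 |
| always_enforce | certain fee −1.2 per reckless choice | −1.42 |
| mostly_enforce | fee lottery −1.2 w.p. 0.95, +24 w.p. 0.05 (EV +0.06) | −0.16 |

All lottery events (base, exposure, fee) are drawn **independently per
player, per option, per trial**. The coupling of the 2% events in the
original computerized game is unreported; independence is the configuration
under which the sampler-model predictions reproduce the published
prediction table (a paired/coupled draw makes Reckless ex-post dominant in
the basic game and collapses the naive-sampler prediction well below 0.09).
Unused draws are consumed anyway so that a fixed seed yields the same event
stream in every condition.

Feedback is full: after each trial every player sees the obtained payoff
and the forgone payoff — the payoff they would have received had they alone
switched, with everyone else's choices and all realized draws held fixed.
In particular a sole reckless player's forgone responsible payoff is 0,
because their switching would make the whole group responsible. This
counterfactual rule is verified exhaustively (all 16 choice profiles × all
rare/common draw combinations, every condition).

## Behavioral models

**Naive sampler (k = 5).** Responsible on trial 1. Afterwards: draw k trial
indices uniformly *with replacement* from the history (paired — a sampled
trial contributes both options' payoffs), and pick the option with the
higher sample mean; exact ties are a fair coin. With-replacement sampling
handles histories shorter than k uniformly; "best in the sample" is
operationalized as best sample mean (identical to best sample sum). The
model has no noise: an option that strictly dominates in every record is
chosen with probability 1. Reliance on a 5-item sample underweights the 2%
loss: the probability it appears in the sample is 1 − 0.98⁵ ≈ 0.096.

**SAW (K = 9, ω = 0.5, ε = 0.4).** A generalization that adds choice noise
and sensitivity to average payoffs. With probability ε the choice is
uniformly random; otherwise each option is scored as
ω · (grand mean over the full history) + (1 − ω) · (paired mean over K
sampled trials) and the argmax is chosen. Responsible on trial 1 (stated in
the source only for the naive sampler; applied to SAW for uniformity). The
published SAW specification is not fully public, so this functional form is
a reconstruction; its predictions are held to qualitative standards only
(see Limitations).

**Exact choice oracle.** `choice_probability_oracle` computes
P(Responsible) exactly by enumerating sample *compositions* over the
distinct experience records with multinomial weights — mathematically
identical to enumerating all nᵏ index tuples but feasible whenever the
history has few distinct rows (it raises when the composition count exceeds
2·10⁵). This makes closed-form cases such as 1 − (59/60)⁵ on a 60-record
history exactly checkable, and anchors Monte-Carlo tests of both samplers
(3σ binomial tolerance on an 11-history battery).

**Cognitive Hierarchy (τ = 1.54).** Reasoning levels are Poisson(τ),
truncated at level 12 and renormalized (the rate is stable to < 10⁻⁴ for
any truncation ≥ 8). Level 0 randomizes uniformly; level k ≥ 1
best-responds in EV to the renormalized distribution of levels < k,
treating its three partners as independently responsible with the belief
probability implied by that distribution; EV ties (never binding at the
printed constants) go to Responsible. Predictions: 0.11 (basic),
0.89 (alert), 0.89 (always_enforce). For mostly_enforce the standard model
yields 0.11, not the published 0.89: reckless EV (−0.16) beats responsible
EV against any substantially reckless belief, so level 1 and everything
above it cascade to Reckless. The published cell presumably derives from an
unpublished supplementary computation; `reproduce_table1` reports the cell
and flags it as a known discrepancy rather than contorting the model.

## Simulation harness

`predict_rate` runs `n_groups` independent 4-agent groups for 60 trials and
averages per-group mean responsible proportions; the default n_groups =
2000 puts the Monte-Carlo standard error of a rate near 0.002–0.004, well
below the 2-decimal precision at which predictions are compared. Prediction
simulations use ideal agents — no timeouts, no penalties. Group g of a run
seeded with `seed` uses `SeedSequence(entropy=seed, spawn_key=(g, 0))`
(game stream) and `(g, 1)` (timeout stream), so enlarging a run extends
rather than reshuffles it, and every artifact is bit-reproducible from its
manifest. Under `always_enforce` the all-responsible profile is absorbing
for the naive sampler (responsible pays a certain 0 while every forgone
reckless payoff is negative), so its simulated rate is exactly 1 for every
seed.

## Synthetic experiment layer

`generate_experiment` adds the design frame of the human studies on top of
the same engine: groups of 4, 60 trials, and i.i.d. per-trial timeouts
(default rate 0.05 — no timeout statistics were published; configurable)
that auto-submit the participant's previous choice (Responsible on trial 1)
with a −2-point penalty. Penalties affect earnings only; they never enter
the experienced option payoffs. Payment: $1 show-up, $2 if strictly more
than 40 of the 60 choices are on time, and a $1 bonus awarded with
probability linear in total points between the condition's minimal and
maximal attainable session totals (clipped to [0, 1]) — the published
points-to-bonus mapping is unspecified, so this linear rule is a documented
stand-in carrying no acceptance burden. The 12 s / 20 s response limits are
stored as metadata only.

These datasets exercise the analysis pipeline; they do not emulate human
idiosyncrasies (prosociality, shared guilt, attrition, reaction times), so
agreement of pipeline output with sampler-model predictions says nothing
about fit to real behavior.

## Analysis pipeline

The unit of analysis is the **group**: participant rates (proportion of 60
trials responsible) average to group rates, and condition means/SDs are
taken across group rates — the degrees of freedom of the published
group-level contrasts (≈ 22–24 for 12 vs 13 groups) imply this convention,
though it is inferred rather than stated. Contrasts use the Welch
unequal-variance t-test with Welch–Satterthwaite degrees of freedom,
implemented directly from the textbook formulas (cross-checked against
scipy's `ttest_ind(equal_var=False)` to 10⁻¹⁰) with the zero-variance
degenerate case routed to t = 0 and pooled df. Differences and confidence
intervals are reported in percentage points as (second − first); signs are
presentation-only. Learning curves split the session into 5 blocks of 12
trials. Timed-out trials count as ordinary submitted choices.

## Problem sizes and numerical choices

- Prediction cells: 2000 groups (500 × 5 seeds for the absorbing
  always-enforce cell); qualitative SAW checks use 1000 groups.
- Monte-Carlo vs oracle tests: 2 × 10⁴ draws per history, 3σ binomial
  tolerance.
- The 20-seed qualitative replication uses seeds 0–19 with fixed
  per-condition offsets; basic-vs-alert non-significance is a null effect,
  so ≈ 1 in 20 seeds is expected to cross α = 0.05 by chance.
- Lottery probabilities must sum to 1 within 10⁻¹²; sampler ties are broken
  by a fair coin (measure-zero-rare at these payoff constants but defined).

## Limitations

- SAW is a reconstruction. Under it the always-enforce rate cannot exceed
  1 − ε/2 = 0.8 (vs the published 0.87), and the alert rate comes out near
  0.38 — above the 0.35 qualitative bound expected of it, driven by the
  grand-mean term after early rare losses. The qualitative ordering
  always_enforce > mostly_enforce > max(basic, alert) does hold. The
  corresponding test records this state honestly rather than adjusting the
  model.
- The published human responsible rates (9%/9%/85%/60%) and t statistics
  depend on undeposited data and are emulated only qualitatively.
- Payoff probabilities are static; no epidemic dynamics, no voluntary app
  adoption, no parameter fitting.
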