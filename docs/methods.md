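# Methods

## The game

Six players, two fixed subgroups of three. Each round every player allocates
one coin to exactly one of: the global pot, their own subgroup's local pot,
the other subgroup's local pot, or their own pocket. Thresholds are 4 coins
(global) and 2 coins (each local pot). When a pot reaches its threshold,
*every member of the corresponding group* receives that pot's payout,
regardless of where their own coin went; a kept coin always pays its keeper
1 coin. A cross-subgroup investment is credited to the other pot and counts
toward that pot's threshold, but pays the investor nothing (the investor is
not a member of the rewarded group). Conditions differ only in the action
menu (the global-only condition removes both local investments) and in the
global payout (2.5 instead of 2 in the boosted condition). Payoffs are
multiples of 0.5 and represented as plain binary floats, which encode such
values exactly; equilibrium checks therefore compare payoffs exactly, with
no tolerance.

The engine plays exactly `n_rounds` (default 20). The deceptive "up to 25
rounds" framing sometimes used to suppress end-game behaviour is not
modelled; agents are horizon-blind.

## Pure-strategy Nash enumeration

A labelled profile (one action per player) is a pure Nash equilibrium when
no player can *strictly* increase their own payoff by a unilateral switch to
another allowed action. Enumeration is exhaustive over labelled players
(2⁶ = 64 or 4⁶ = 4096 profiles) rather than over summary classes, because a
summary can be realised by several subgroup compositions and the deviation
check depends on who holds each action. Surviving profiles are collapsed to
`(G, L1, L2, D)` — global investors, coins credited to each local pot,
keepers — and reported in lexicographically descending order of
`(G, L1, L2)` for stable output. Weak equilibria (where some deviation
ties) would be retained under this definition, but none arise: the kept
coin's +1 makes any non-pivotal investment strictly dominated. Cross-pot
investment is strictly dominated by keeping, so it never appears in an
equilibrium — asserted over the full enumeration in the tests. Whether the
summary's L components count cross-subgroup coins is moot at equilibrium
for the same reason; the collapse uses pot-credited counts. Mixed-strategy
equilibria exist (any threshold game has them) but are deliberately out of
scope.

## The synthetic-data generator

The generator produces datasets with the shape and statistical structure of
a three-condition online experiment: 57 groups per condition × 6 players ×
20 rounds of actions, and identity measurements at waves 0, 5, 10, 15, 20.

### Identity

Each agent carries three scores on a 0–100 scale: identity with the global
group, own subgroup, and other subgroup.

*Initialisation.* Observed initial scores have per-condition means/SDs such
as own-local 91.9 ± 12.6 with the mean close to the ceiling, so a normal
*truncated* at those parameters would undershoot the target mean by several
points. Initial scores are therefore drawn from a normal **clipped** to
[0, 100] whose underlying location/scale are solved (censored-normal moment
matching, `scipy.optimize.fsolve` on the closed-form clipped moments) so
that the clipped distribution has exactly the target mean and SD. The
resulting atom at 100 mirrors how slider instruments censor at full
overlap.

*Dynamics.* After every round each score receives a fixed drift (defaults:
−0.76 global, −0.90 own local, −0.74 other local, per round on the 0–100
scale) plus a boost when the corresponding threshold was met (+2.09 global,
+1.35 own local — the performance-cohesion effect), plus an independent
Gaussian innovation (sd 2.0, report variability of the slider), then
clipping to [0, 100]. `update_identity` itself is deterministic (drift +
boost + clip); the innovation is added by the simulator when an RNG is
passed. Without the innovation, wave-to-wave identity changes would be an
exact linear function of success counts and the recovery regressions would
have zero residual variance, which no measured instrument exhibits.

### Behaviour

Round 1 has no history: agents keep with a baseline probability (0.28),
invest in the other local pot with a small fixed probability (0.01), and
otherwise choose global vs own-local by a logistic in
`identity_weight × (score_global − score_own_local)` with slope 0.03 plus
an intercept (0.6) and a payoff tilt (`payoff_weight × (global − local
payout)`), so the boosted condition starts more global.

From round 2 the action is sampled from a softmax over the allowed actions
with utility

```
u(a) = baseline(a)
     + payoff_weight · payout(a)
     + stickiness · 1[a = last action]
     + (cc_linear · c_a + cc_quadratic · c_a²) · 1[a invests]
     + invest_round_drift · (round − 1) · 1[a invests]
     + identity_weight · (score_global − score_own_local) · 1[a = global]
```

where `c_a` is the previous round's coin count in the pot `a` targets.
Defaults: baselines (global −0.7, own local −0.8, other local −3.9, keep
0), `payoff_weight` 0.6, `stickiness` 1.2, `cc_linear` 0.5, `cc_quadratic`
−0.06, `invest_round_drift` −0.06, `identity_weight` 0.03, temperature 1.

The terms encode the qualitative regularities of play in such games:
strong persistence (agents repeat their previous action in ~75% of rounds),
conditional cooperation with an inverted-U response to others' cooperation
(investment is most attractive near the threshold and declines once the pot
is comfortably over it — the negative quadratic), sensitivity to the stake
(this is what makes the boosted global payout pull investment away from the
local pots), a slow erosion of the willingness to invest as the game
progresses (rising defection), and an identity steer on the global-vs-local
margin. The numeric defaults other than the identity parameters were
calibrated once so that the generated aggregates sit in the empirically
realistic region — roughly 45–70% global investment depending on condition,
~30% defection, <1% cross-pot investment, global thresholds met most often
in the global-only condition and least often in the balanced condition —
and then frozen.

### Randomness

One master seed; each (condition, group) pair draws from its own
`numpy.random.SeedSequence(seed, spawn_key=(condition_index, group_index))`
substream, so output is byte-identical under reordering or subsetting of
groups. The manifest records the full configuration; reloading it
regenerates identical tables.

### What the generator does *not* emulate

Participant dropout, comprehension failures, heterogeneous agent types
(everyone shares one parameter vector; real populations mix conditional
cooperators, free-riders and altruists), end-game strategy shifts, and any
dependence of identity on payoffs rather than threshold success. Passing
analysis tests on this data shows the pipeline recovers the generating
process it was pointed at — not that the same estimates would be obtained
on human data.

## Analysis pipeline

* **Group summaries** — one row per group: action proportions over
  player-rounds and threshold success rates over rounds. The local success
  rate averages the two pots. "Local cooperation" counts own-local
  investments only; cross-pot investments (<1%) are treated as noise.
* **Mann–Whitney U** (condition comparisons) — the group is the independent
  unit. Exact null distribution for tie-free samples up to n = 20 per side,
  otherwise midranks with the tie-corrected normal approximation. Statistic
  reported: U for the first sample.
* **Wilcoxon signed-rank** (paired identity comparisons) — zero differences
  dropped; all-zero input raises a degenerate-input error. Statistic: the
  negative-rank sum W⁻.
* **Holm–Bonferroni** — step-down with monotonicity enforcement, capped at
  1, input order restored. Families: the two global-cooperation comparisons
  form one family, the two defection comparisons another, and each
  three-condition set of paired identity tests its own family.
* **Trend models** — the original analyses used cumulative link mixed
  models; here each target action is a binary logistic regression on round,
  condition and their interaction, with group-clustered robust standard
  errors. The estimand (sign and rough per-round magnitude of the trend) is
  preserved; the random-effects ordinal machinery is not reproduced, and
  every fit is labelled accordingly. The local-cooperation model is fitted
  on the two local-capable conditions with the balanced condition as
  reference; the boosted condition's local trend is the Wald test of
  `round + round:boost` from the coefficient covariance.
* **First-round logistic** — global(1) vs own-local(0) on the wave-0
  `score_global − score_own_local` difference, group-clustered errors.
  Constant differences and separated outcomes raise informative errors.
* **Identity models** — per scale (global, own local): the *level* model
  regresses score on round (the marginal trend, mixing drift and
  accumulated boosts) and the *change* model regresses wave-to-wave score
  change on the number of threshold successes in the intervening rounds.
  In the change model the "intercept" column equals the interval length, so
  its coefficient is directly the per-round drift, and the `successes`
  coefficient the per-success boost. Because the 0–100 scale censors,
  transitions *starting* within 12 points of a bound are excluded: selection
  on the starting value is exogenous to everything inside the interval
  (unlike selection on the endpoint, which would bias the fit), and 12
  points covers a score's plausible within-interval excursion (five rounds
  of drift/boost ≈ 6.7 plus ~3 SDs of accumulated innovation noise).
  Participant-clustered robust errors throughout. Two-sided tests
  everywhere; directional claims are read from sign plus two-sided p.

All stages are pure functions of the input tables: identical inputs yield
an identical report.

## Test problem sizes

The statistical acceptance checks run at sizes chosen to balance power and
runtime on a single CPU: parameter-recovery coverage uses 200 seeds at 20
groups per condition (binomial band 178–199 hits out of 200 for a nominal
95% rate); type-I calibration uses 500 seeds of two identical 10-group arms
playing 10 rounds (band 9–41 rejections at α = 0.05). Rank-statistic
oracles enumerate all pairs/ranks for inputs up to n = 8.

## Known limitations

* The CLMM/LME replacement gives comparable trend estimands, not identical
  coefficients to a random-effects ordinal fit.
* The censoring guard in the identity change model discards 30–50% of
  transitions when scores start near the ceiling (as they do with the
  default initial distributions); estimates remain mildly conservative if
  scores re-enter the guard band mid-interval.
* With a single shared parameter vector the generator cannot reproduce the
  bimodality of per-group cooperation observed in heterogeneous
  populations.
* Schema-compatible ingestion of externally collected CSVs is supported
  (`mlpgg validate`, `mlpgg analyze`) but has only been exercised against
  generated data.
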