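# mlpgg — multilevel threshold public goods game

`mlpgg` is a research toolkit for studying cooperation at competing scales.
It implements a repeated, multilevel *threshold* public goods game: six
players form a global group split into two local subgroups of three, and
each round every player holds one coin to keep or to invest in the global
pot, their own subgroup's pot, or the other subgroup's pot. A pot pays out
to every member of the corresponding group once it reaches its threshold
(4 coins global, 2 coins local); keeping the coin always pays 1. Three
experimental conditions vary the menu and the stakes:

| condition     | actions                  | global payout | local payout |
|---------------|--------------------------|---------------|--------------|
| global only   | invest global, keep      | +2            | —            |
| balanced      | all four                 | +2            | +2           |
| global boost  | all four                 | +2.5          | +2           |

The package is aimed at behavioural game theorists and social psychologists
who want to (a) reason about the game's strategic structure, (b) generate
realistic synthetic experiment data, and (c) run a group-level hypothesis
pipeline — without access to human data.

Four library layers, one CLI:

* **`mlpgg.game`** — the payoff engine: pot crediting (a cross-subgroup
  investment counts toward the *other* pot), threshold flags, per-player
  payoffs, coin↔GBP conversion (1 coin = £0.05).
* **`mlpgg.equilibrium`** — exhaustive pure-strategy Nash enumeration over
  all labelled profiles (2⁶ or 4⁶), collapsed to the summary
  `(G, L1, L2, D)` = (global investors, coins in each local pot, keepers).
  A profile is an equilibrium when no player has a *strictly* profitable
  unilateral deviation. Mixed-strategy equilibria exist but are out of
  scope.
* **`mlpgg.simulate`** — a behavioural simulator: conditional cooperators
  with softmax policies (stickiness, an inverted-U response to last round's
  investor counts, payoff sensitivity) whose three group-identity scores
  (0–100) co-evolve with play — drifting down each round and boosted when
  the corresponding threshold is met.
* **`mlpgg.analysis`** — the pre-registered pipeline: Mann–Whitney U tests
  on group-level rates, Wilcoxon signed-rank tests on paired identity
  scores, Holm–Bonferroni step-down correction, trend regressions over
  rounds with group-clustered robust errors, a first-round identity
  logistic, and identity-dynamics models that recover the drift and the
  performance-cohesion boost.

## Worked example

```python
from mlpgg import GLOBAL_ONLY, enumerate_pure_nash, SimConfig, generate_dataset
from mlpgg.analysis import group_summaries, mann_whitney, run_preregistered_suite

report = enumerate_pure_nash(GLOBAL_ONLY)
print("pure Nash classes (G, L1, L2, D):", list(report.classes))

ds = generate_dataset(SimConfig(n_groups_per_condition=20, seed=42))
summaries = group_summaries(ds.actions)
print(summaries.groupby("condition")["prop_global"].mean().round(3).to_string())

a = summaries[summaries.condition == "global_only"]["prop_global"]
b = summaries[summaries.condition == "balanced"]["prop_global"]
res = mann_whitney(a, b)
print(f"U = {res.statistic:.0f}, p = {res.p_raw:.2g}")

rep = run_preregistered_suite(ds.actions, ds.identity)["hypotheses"]
print("first-round identity slope:", round(rep["H5"]["params"]["identity_diff"], 3))
```

prints

```
pure Nash classes (G, L1, L2, D): [(4, 0, 0, 2), (0, 0, 0, 6)]
balanced        0.473
global_boost    0.642
global_only     0.716
U = 368, p = 5.7e-06
first-round identity slope: 0.024
```

Reading the output: in the global-only condition the only pure equilibria
are a minimal winning coalition of 4 investors (with 2 free-riders) and
full defection. In the simulated experiment, groups invest globally less
often when a local option exists (0.473 vs 0.716 of player-rounds), the U
test on 20 groups per side rejects decisively, and the logistic slope of
first-round global-vs-local choice on the initial identity difference is
recovered near its generating value of 0.03.

The same pipeline is scriptable from a shell:

```bash
mlpgg equilibria --condition all
mlpgg simulate --seed 42 --groups 57 --out data/
mlpgg analyze --actions data/actions.csv --identity data/identity.csv --out report.json
mlpgg replicate --seed 42 --out bundle/      # everything, incl. figure tables
```

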