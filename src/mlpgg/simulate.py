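"""Synthetic-experiment generator: conditional cooperators with co-evolving
group identity.

Each simulated participant carries three identity scores on a 0–100 scale
(global group, own local subgroup, other local subgroup), initialised from
condition-specific truncated normals. Behaviour follows a softmax policy
over the condition's allowed actions whose utilities combine

* a baseline log-propensity per action,
* stickiness on the previous round's own action,
* a conditional-cooperation term ``cc_linear * c + cc_quadratic * c**2``
  where ``c`` is the previous round's coin count in the pot the candidate
  action targets (the negative quadratic makes investment probability peak
  at an interior cooperation level and fall off once enough others invest),
* an identity steer: the global-investment utility gains
  ``identity_weight * (score_global - score_own_local)``.

In the first round there is no history: a baseline keep probability applies
first, a small fixed probability covers the (rare, payoff-less) cross-local
investment, and the remaining global vs own-local choice is logistic in the
identity difference with slope ``identity_weight``.

After every round each identity score drifts by a fixed per-round amount and
gains a boost when the corresponding threshold was met (performance-cohesion
effect); the simulator adds a Gaussian innovation to each score (report
variability of the slider instrument) and clips to [0, 100]. Identity is
snapshotted at waves 0, 5, 10, 15, 20 by default.

Defaults reproduce the calibrated study conditions: 3 conditions x 57
groups x 6 players x 20 rounds, identity dynamics with per-round drifts
(-0.76, -0.90, -0.74), success boosts (2.09 global, 1.35 local), first-round
identity slope 0.03, and initial identity distributions per condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .game import (
    Action,
    ActionProfile,
    ConditionSpec,
    CONDITIONS,
    DEFAULT_STRUCTURE,
    GroupStructure,
    N_PLAYERS,
    RoundOutcome,
    round_outcome,
)

ACTIONS_CSV_COLUMNS = [
    "group_id",
    "condition",
    "round",
    "player_id",
    "subgroup",
    "action",
    "global_pot",
    "local_pot_1",
    "local_pot_2",
    "kept",
    "global_met",
    "local1_met",
    "local2_met",
    "payoff",
]

IDENTITY_CSV_COLUMNS = [
    "player_id",
    "group_id",
    "condition",
    "wave",
    "score_global",
    "score_own_local",
    "score_other_local",
]


# ---------------------------------------------------------------------------
# Parameters


@dataclass(frozen=True)
class AgentParams:
    """Behavioural propensities of one simulated participant.

    Baselines are log-propensities on the softmax scale; the other-local
    baseline is strongly negative because cross-subgroup investment pays
    nothing and is observed only as rare noise (~0.6% of rounds).
    """

    baseline: Mapping[Action, float] = field(
        default_factory=lambda: {
            Action.INVEST_GLOBAL: -0.7,
            Action.INVEST_OWN_LOCAL: -0.8,
            Action.INVEST_OTHER_LOCAL: -3.9,
            Action.KEEP: 0.0,
        }
    )
    stickiness: float = 1.2
    cc_linear: float = 0.5
    cc_quadratic: float = -0.06
    identity_weight: float = 0.03
    payoff_weight: float = 0.6
    invest_round_drift: float = -0.06
    noise_temperature: float = 1.0
    first_round_keep_prob: float = 0.28
    first_round_other_prob: float = 0.01
    first_round_intercept: float = 0.6

    def __post_init__(self) -> None:
        if self.noise_temperature <= 0:
            raise ValueError("noise_temperature must be positive")


@dataclass(frozen=True)
class IdentityDynamics:
    """Per-round drift and success boosts of the three identity scores."""

    drift_global: float = -0.76
    drift_own_local: float = -0.90
    drift_other_local: float = -0.74
    boost_global: float = 2.09
    boost_local: float = 1.35
    noise_sd: float = 2.0


@dataclass(frozen=True)
class IdentityState:
    """Three identity scores of one participant, each clipped to [0, 100]."""

    score_global: float
    score_own_local: float
    score_other_local: float

    def clipped(self) -> "IdentityState":
        return IdentityState(
            score_global=min(100.0, max(0.0, self.score_global)),
            score_own_local=min(100.0, max(0.0, self.score_own_local)),
            score_other_local=min(100.0, max(0.0, self.score_other_local)),
        )


# Initial identity means and SDs per condition (own local, other local,
# global), measured on the 0-100 slider before the first round.
_TABLE_INITIAL = {
    "global_only": {"own_local": (91.9, 12.6), "other_local": (62.6, 23.4), "global": (90.5, 12.1)},
    "balanced": {"own_local": (93.4, 11.6), "other_local": (47.2, 27.3), "global": (89.9, 11.5)},
    "global_boost": {"own_local": (93.2, 10.9), "other_local": (50.1, 27.0), "global": (90.7, 11.9)},
}


@dataclass(frozen=True)
class InitialIdentityDistribution:
    """Target mean and SD of the three initial scores on the 0-100 scale.

    ``params[target] = (mean, sd)`` for targets own_local / other_local /
    global. Scores are drawn from a normal clipped to [0, 100] whose
    underlying location/scale are solved so the *clipped* distribution has
    exactly the requested moments. Plain truncation at the stated moments
    would drag the sample mean several points below the target when the mean
    sits close to the ceiling (e.g. 91.9 with SD 12.6); clipping instead
    places an atom at the endpoint, which mirrors how slider instruments
    censor at full overlap.
    """

    params: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for target, (mean, sd) in self.params.items():
            if not 0.0 <= mean <= 100.0:
                raise ValueError(f"{target}: mean {mean} outside [0, 100]")
            if sd < 0:
                raise ValueError(f"{target}: sd must be non-negative, got {sd}")

    @classmethod
    def for_condition(cls, condition: str) -> "InitialIdentityDistribution":
        return cls(params=dict(_TABLE_INITIAL[condition]))


def _clipped_normal_moments(mu: float, sigma: float, lo: float = 0.0, hi: float = 100.0):
    """Mean and SD of min(hi, max(lo, N(mu, sigma))), in closed form."""
    from scipy import stats

    a = (lo - mu) / sigma
    b = (hi - mu) / sigma
    Pa, Pb = stats.norm.cdf(a), stats.norm.cdf(b)
    pa, pb = stats.norm.pdf(a), stats.norm.pdf(b)
    P = Pb - Pa
    mean = lo * Pa + hi * (1.0 - Pb) + mu * P + sigma * (pa - pb)
    ez2 = (mu**2) * P + 2 * mu * sigma * (pa - pb) + sigma**2 * (P + a * pa - b * pb)
    e2 = lo**2 * Pa + hi**2 * (1.0 - Pb) + ez2
    return mean, math.sqrt(max(e2 - mean * mean, 0.0))


_CLIP_PARAM_CACHE: dict[tuple[float, float], tuple[float, float]] = {}


def _clipped_normal_params(mean: float, sd: float) -> tuple[float, float]:
    """Underlying (mu, sigma) whose [0, 100]-clipped moments are (mean, sd)."""
    key = (mean, sd)
    if key not in _CLIP_PARAM_CACHE:
        from scipy import optimize

        def residual(x):
            m, s = _clipped_normal_moments(x[0], math.exp(x[1]))
            return [m - mean, s - sd]

        sol, _, ier, msg = optimize.fsolve(
            residual, [mean, math.log(sd * 1.3)], full_output=True
        )
        if ier != 1:
            raise RuntimeError(f"moment matching failed for ({mean}, {sd}): {msg}")
        _CLIP_PARAM_CACHE[key] = (float(sol[0]), float(math.exp(sol[1])))
    return _CLIP_PARAM_CACHE[key]


def _identity_draw(mean: float, sd: float, rng: np.random.Generator) -> float:
    """One clipped-normal draw whose population mean/SD equal (mean, sd).
    sd == 0 degenerates to the mean."""
    if sd == 0.0:
        return float(min(100.0, max(0.0, mean)))
    mu, sigma = _clipped_normal_params(mean, sd)
    return float(min(100.0, max(0.0, rng.normal(mu, sigma))))


def init_identity(
    cond: ConditionSpec,
    rng: np.random.Generator,
    dist: InitialIdentityDistribution | None = None,
) -> IdentityState:
    """Draw one participant's three initial identity scores independently."""
    if dist is None:
        dist = InitialIdentityDistribution.for_condition(cond.name)
    return IdentityState(
        score_global=_identity_draw(*dist.params["global"], rng),
        score_own_local=_identity_draw(*dist.params["own_local"], rng),
        score_other_local=_identity_draw(*dist.params["other_local"], rng),
    )


# ---------------------------------------------------------------------------
# Policies


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def first_round_policy(
    identity: IdentityState,
    cond: ConditionSpec,
    params: AgentParams,
    rng: np.random.Generator,
) -> Action:
    """Sample a first-round action with no history to condition on.

    Keep happens with a fixed baseline probability; among investors a small
    fixed share goes to the other local pot (when allowed) and the global vs
    own-local split is logistic in ``identity_weight * (global - own local)``.
    In the global-only condition every investment is global.
    """
    if rng.random() < params.first_round_keep_prob:
        return Action.KEEP
    if not cond.has_local:
        return Action.INVEST_GLOBAL
    if rng.random() < params.first_round_other_prob:
        return Action.INVEST_OTHER_LOCAL
    diff = identity.score_global - identity.score_own_local
    payoff_tilt = params.payoff_weight * (cond.payoff_global - (cond.payoff_local or 0.0))
    p_global = _sigmoid(
        params.first_round_intercept + params.identity_weight * diff + payoff_tilt
    )
    return Action.INVEST_GLOBAL if rng.random() < p_global else Action.INVEST_OWN_LOCAL


def _target_pot_count(action: Action, subgroup: int, last: RoundOutcome) -> int:
    """Previous-round coin count in the pot that ``action`` would feed."""
    if action is Action.INVEST_GLOBAL:
        return last.pots.global_pot
    if action is Action.INVEST_OWN_LOCAL:
        return last.pots.local_pot(subgroup)
    if action is Action.INVEST_OTHER_LOCAL:
        return last.pots.local_pot(3 - subgroup)
    raise ValueError(f"{action} does not target a pot")


def _payoff_increment(action: Action, cond: ConditionSpec) -> float:
    """The pot payout an action's target would deliver if its threshold is
    met (the keeper's increment for KEEP); the cross-local pot pays the
    investor nothing."""
    if action is Action.INVEST_GLOBAL:
        return cond.payoff_global
    if action is Action.INVEST_OWN_LOCAL:
        return cond.payoff_local or 0.0
    if action is Action.KEEP:
        return cond.payoff_keep
    return 0.0


def step_policy(
    identity: IdentityState,
    last_action: Action,
    last_round: RoundOutcome,
    subgroup: int,
    cond: ConditionSpec,
    params: AgentParams,
    rng: np.random.Generator,
    round_no: int = 2,
) -> Action:
    """Sample an action for rounds >= 2 from the softmax policy.

    Besides stickiness, conditional cooperation and the identity steer, the
    utilities carry a payoff-sensitivity term (weight times the target pot's
    payout increment — this is what makes the boosted global payoff attract
    investment) and a per-round drift on investment utilities that erodes
    cooperation as the game progresses.
    """
    utilities = []
    diff = identity.score_global - identity.score_own_local
    for action in cond.allowed_actions:
        u = params.baseline[action]
        u += params.payoff_weight * _payoff_increment(action, cond)
        if action is last_action:
            u += params.stickiness
        if action is not Action.KEEP:
            c = _target_pot_count(action, subgroup, last_round)
            u += params.cc_linear * c + params.cc_quadratic * c * c
            u += params.invest_round_drift * (round_no - 1)
        if action is Action.INVEST_GLOBAL:
            u += params.identity_weight * diff
        utilities.append(u / params.noise_temperature)
    m = max(utilities)
    weights = [math.exp(u - m) for u in utilities]
    total = sum(weights)
    r = rng.random() * total
    acc = 0.0
    for action, w in zip(cond.allowed_actions, weights):
        acc += w
        if r < acc:
            return action
    return cond.allowed_actions[-1]


def update_identity(
    identity: IdentityState,
    outcome: RoundOutcome,
    subgroup: int,
    dynamics: IdentityDynamics = IdentityDynamics(),
    rng: np.random.Generator | None = None,
) -> IdentityState:
    """Apply one round's drift, success boosts and clipping.

    Deterministic unless ``rng`` is given, in which case each score also
    receives an independent Gaussian innovation with sd ``dynamics.noise_sd``
    before clipping.
    """
    g = identity.score_global + dynamics.drift_global
    own = identity.score_own_local + dynamics.drift_own_local
    other = identity.score_other_local + dynamics.drift_other_local
    if outcome.flags.global_met:
        g += dynamics.boost_global
    if outcome.flags.own_local_met(subgroup):
        own += dynamics.boost_local
    if rng is not None and dynamics.noise_sd > 0:
        g += rng.normal(0.0, dynamics.noise_sd)
        own += rng.normal(0.0, dynamics.noise_sd)
        other += rng.normal(0.0, dynamics.noise_sd)
    return IdentityState(g, own, other).clipped()


# ---------------------------------------------------------------------------
# Simulation


@dataclass(frozen=True)
class SimConfig:
    """Shape and parameters of one synthetic experiment."""

    n_groups_per_condition: int = 57
    n_rounds: int = 20
    identity_waves: tuple[int, ...] = (0, 5, 10, 15, 20)
    seed: int = 0
    conditions: tuple[str, ...] = ("global_only", "balanced", "global_boost")
    agent_params: AgentParams = field(default_factory=AgentParams)
    identity_dynamics: IdentityDynamics = field(default_factory=IdentityDynamics)
    # condition name -> InitialIdentityDistribution; None = per-condition defaults
    initial_identity: Mapping[str, InitialIdentityDistribution] | None = None

    def __post_init__(self) -> None:
        if 0 not in self.identity_waves:
            raise ValueError("wave 0 (pre-game measurement) must be present")
        if any(w < 0 or w > self.n_rounds for w in self.identity_waves):
            raise ValueError("identity waves must lie within [0, n_rounds]")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition {c!r}")

    def to_dict(self) -> dict:
        return {
            "n_groups_per_condition": self.n_groups_per_condition,
            "n_rounds": self.n_rounds,
            "identity_waves": list(self.identity_waves),
            "seed": self.seed,
            "conditions": list(self.conditions),
            "agent_params": {
                "baseline": {a.value: v for a, v in self.agent_params.baseline.items()},
                "stickiness": self.agent_params.stickiness,
                "cc_linear": self.agent_params.cc_linear,
                "cc_quadratic": self.agent_params.cc_quadratic,
                "identity_weight": self.agent_params.identity_weight,
                "payoff_weight": self.agent_params.payoff_weight,
                "invest_round_drift": self.agent_params.invest_round_drift,
                "noise_temperature": self.agent_params.noise_temperature,
                "first_round_keep_prob": self.agent_params.first_round_keep_prob,
                "first_round_other_prob": self.agent_params.first_round_other_prob,
                "first_round_intercept": self.agent_params.first_round_intercept,
            },
            "identity_dynamics": {
                "drift_global": self.identity_dynamics.drift_global,
                "drift_own_local": self.identity_dynamics.drift_own_local,
                "drift_other_local": self.identity_dynamics.drift_other_local,
                "boost_global": self.identity_dynamics.boost_global,
                "boost_local": self.identity_dynamics.boost_local,
                "noise_sd": self.identity_dynamics.noise_sd,
            },
            "initial_identity": (
                None
                if self.initial_identity is None
                else {
                    cond: {t: list(ms) for t, ms in dist.params.items()}
                    for cond, dist in self.initial_identity.items()
                }
            ),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        ap = d.get("agent_params", {})
        idd = d.get("identity_dynamics", {})
        agent = AgentParams(
            baseline={Action(a): float(v) for a, v in ap["baseline"].items()}
            if "baseline" in ap
            else AgentParams().baseline,
            **{k: ap[k] for k in (
                "stickiness", "cc_linear", "cc_quadratic", "identity_weight",
                "payoff_weight", "invest_round_drift", "noise_temperature",
                "first_round_keep_prob", "first_round_other_prob",
                "first_round_intercept",
            ) if k in ap},
        )
        dynamics = IdentityDynamics(**idd)
        init = d.get("initial_identity")
        initial = (
            None
            if init is None
            else {
                cond: InitialIdentityDistribution(
                    params={t: (float(m), float(s)) for t, (m, s) in dd.items()}
                )
                for cond, dd in init.items()
            }
        )
        return cls(
            initial_identity=initial,
            n_groups_per_condition=int(d.get("n_groups_per_condition", 57)),
            n_rounds=int(d.get("n_rounds", 20)),
            identity_waves=tuple(d.get("identity_waves", (0, 5, 10, 15, 20))),
            seed=int(d.get("seed", 0)),
            conditions=tuple(d.get("conditions", ("global_only", "balanced", "global_boost"))),
            agent_params=agent,
            identity_dynamics=dynamics,
        )


@dataclass
class TidyDatasets:
    """Round-level actions and wave-level identity tables, plus a manifest."""

    actions: pd.DataFrame
    identity: pd.DataFrame
    manifest: dict


def simulate_group(
    cond: ConditionSpec,
    config: SimConfig,
    rng: np.random.Generator,
    group_id: str = "g0",
    structure: GroupStructure = DEFAULT_STRUCTURE,
) -> tuple[list[dict], list[dict]]:
    """Simulate one 6-player group for ``config.n_rounds`` rounds.

    Returns (action rows, identity rows) as lists of dicts with the tidy CSV
    schemas. Identity is updated after every round and snapshotted at the
    configured waves; wave 0 is the pre-game measurement.
    """
    params = config.agent_params
    dynamics = config.identity_dynamics
    dist = (config.initial_identity or {}).get(cond.name)
    identities = [init_identity(cond, rng, dist) for _ in range(N_PLAYERS)]
    player_ids = [f"{group_id}_p{i}" for i in range(N_PLAYERS)]

    action_rows: list[dict] = []
    identity_rows: list[dict] = []

    def snapshot(wave: int) -> None:
        for i in range(N_PLAYERS):
            identity_rows.append(
                {
                    "player_id": player_ids[i],
                    "group_id": group_id,
                    "condition": cond.name,
                    "wave": wave,
                    "score_global": identities[i].score_global,
                    "score_own_local": identities[i].score_own_local,
                    "score_other_local": identities[i].score_other_local,
                }
            )

    if 0 in config.identity_waves:
        snapshot(0)

    last_actions: list[Action] = []
    last_outcome: RoundOutcome | None = None
    for round_no in range(1, config.n_rounds + 1):
        if round_no == 1:
            actions = [
                first_round_policy(identities[i], cond, params, rng)
                for i in range(N_PLAYERS)
            ]
        else:
            actions = [
                step_policy(
                    identities[i],
                    last_actions[i],
                    last_outcome,
                    structure.subgroup_of[i],
                    cond,
                    params,
                    rng,
                    round_no=round_no,
                )
                for i in range(N_PLAYERS)
            ]
        profile = ActionProfile(tuple(actions), structure)
        outcome = round_outcome(profile, cond)
        for i in range(N_PLAYERS):
            action_rows.append(
                {
                    "group_id": group_id,
                    "condition": cond.name,
                    "round": round_no,
                    "player_id": player_ids[i],
                    "subgroup": structure.subgroup_of[i],
                    "action": actions[i].value,
                    "global_pot": outcome.pots.global_pot,
                    "local_pot_1": outcome.pots.local_pot_1,
                    "local_pot_2": outcome.pots.local_pot_2,
                    "kept": outcome.pots.kept,
                    "global_met": outcome.flags.global_met,
                    "local1_met": outcome.flags.local_1_met,
                    "local2_met": outcome.flags.local_2_met,
                    "payoff": outcome.payoffs[i],
                }
            )
        identities = [
            update_identity(identities[i], outcome, structure.subgroup_of[i], dynamics, rng)
            for i in range(N_PLAYERS)
        ]
        if round_no in config.identity_waves:
            snapshot(round_no)
        last_actions = actions
        last_outcome = outcome

    return action_rows, identity_rows


def _group_rng(seed: int, condition_index: int, group_index: int) -> np.random.Generator:
    """Independent substream per group, stable under reordering."""
    ss = np.random.SeedSequence(seed, spawn_key=(condition_index, group_index))
    return np.random.default_rng(ss)


def generate_dataset(config: SimConfig) -> TidyDatasets:
    """Simulate the full experiment: every condition x group combination.

    Each group draws from its own RNG substream derived from the master seed
    and the (condition, group) indices, so the output is deterministic and
    independent of iteration order.
    """
    action_rows: list[dict] = []
    identity_rows: list[dict] = []
    for ci, cond_name in enumerate(config.conditions):
        cond = CONDITIONS[cond_name]
        for gi in range(config.n_groups_per_condition):
            group_id = f"{cond_name}_g{gi:03d}"
            rng = _group_rng(config.seed, ci, gi)
            a_rows, i_rows = simulate_group(cond, config, rng, group_id=group_id)
            action_rows.extend(a_rows)
            identity_rows.extend(i_rows)
    actions = pd.DataFrame(action_rows, columns=ACTIONS_CSV_COLUMNS)
    identity = pd.DataFrame(identity_rows, columns=IDENTITY_CSV_COLUMNS)
    manifest = {"config": config.to_dict(), "seed": config.seed, "package": "mlpgg 0.1.0"}
    return TidyDatasets(actions=actions, identity=identity, manifest=manifest)
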