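"""Payoff engine for a multilevel threshold public goods game.

Six players form one global group split into two fixed local subgroups of
three. Each round every player holds one coin and either keeps it or invests
it in the global pot, their own subgroup's local pot, or the other subgroup's
local pot. A pot "pays out" when it reaches its threshold (4 coins for the
global pot, 2 for each local pot): every member of the corresponding group
then receives the pot's payoff increment, regardless of where their own coin
went. Keeping the coin always pays the keeper 1 coin. Coins convert to
currency at a fixed rate.

Three experimental conditions share this structure and differ only in the
available actions and the global increment:

==============  =======================  =============  ============
condition       allowed actions          global payoff  local payoff
==============  =======================  =============  ============
global_only     invest_global, keep      2.0            (none)
balanced        all four                 2.0            2.0
global_boost    all four                 2.5            2.0
==============  =======================  =============  ============

All payoff values are multiples of 0.5 and therefore exact as binary floats;
payoff comparisons (e.g. in the Nash check) are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

N_PLAYERS = 6
COIN_VALUE_GBP = 0.05


class Action(str, Enum):
    """One player's choice for their single coin in one round."""

    INVEST_GLOBAL = "invest_global"
    INVEST_OWN_LOCAL = "invest_own_local"
    INVEST_OTHER_LOCAL = "invest_other_local"
    KEEP = "keep"


INVEST_ACTIONS = (
    Action.INVEST_GLOBAL,
    Action.INVEST_OWN_LOCAL,
    Action.INVEST_OTHER_LOCAL,
)


class GameError(ValueError):
    """Invalid profile, action, or condition configuration."""


@dataclass(frozen=True)
class GroupStructure:
    """Fixed assignment of the six players to two local subgroups of three.

    ``subgroup_of[i]`` is 1 or 2; the assignment never changes across rounds.
    """

    subgroup_of: tuple[int, ...] = (1, 1, 1, 2, 2, 2)

    def __post_init__(self) -> None:
        if len(self.subgroup_of) != N_PLAYERS:
            raise GameError(f"expected {N_PLAYERS} players, got {len(self.subgroup_of)}")
        counts = {g: self.subgroup_of.count(g) for g in (1, 2)}
        if counts != {1: 3, 2: 3}:
            raise GameError(f"each subgroup must have exactly 3 members, got {counts}")

    def other_subgroup(self, player: int) -> int:
        return 3 - self.subgroup_of[player]

    def members(self, subgroup: int) -> tuple[int, ...]:
        return tuple(i for i, g in enumerate(self.subgroup_of) if g == subgroup)


DEFAULT_STRUCTURE = GroupStructure()


@dataclass(frozen=True)
class ConditionSpec:
    """Thresholds, payoff increments and allowed actions of one condition."""

    name: str
    allowed_actions: tuple[Action, ...]
    global_threshold: int = 4
    local_threshold: int = 2
    payoff_global: float = 2.0
    payoff_local: float | None = 2.0
    payoff_keep: float = 1.0
    coin_value_gbp: float = COIN_VALUE_GBP

    def __post_init__(self) -> None:
        if self.global_threshold > N_PLAYERS or self.local_threshold > N_PLAYERS:
            raise GameError("thresholds cannot exceed the number of players")
        has_local_action = Action.INVEST_OWN_LOCAL in self.allowed_actions
        if has_local_action != (self.payoff_local is not None):
            raise GameError("payoff_local must be defined iff local investment is allowed")
        for v in (self.payoff_global, self.payoff_keep, self.payoff_local or 0.0):
            if v < 0:
                raise GameError("payoff increments must be non-negative")

    @property
    def has_local(self) -> bool:
        return self.payoff_local is not None

    def validate_action(self, player: int, action: Action) -> None:
        if action not in self.allowed_actions:
            raise GameError(
                f"action {action.value!r} by player {player} is not allowed "
                f"in condition {self.name!r}"
            )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "global_threshold": self.global_threshold,
            "local_threshold": self.local_threshold,
            "payoff_global": self.payoff_global,
            "payoff_local": self.payoff_local,
            "payoff_keep": self.payoff_keep,
            "allowed_actions": [a.value for a in self.allowed_actions],
            "coin_value_gbp": self.coin_value_gbp,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ConditionSpec":
        return cls(
            name=d["name"],
            allowed_actions=tuple(Action(a) for a in d["allowed_actions"]),
            global_threshold=int(d.get("global_threshold", 4)),
            local_threshold=int(d.get("local_threshold", 2)),
            payoff_global=float(d.get("payoff_global", 2.0)),
            payoff_local=(None if d.get("payoff_local") is None else float(d["payoff_local"])),
            payoff_keep=float(d.get("payoff_keep", 1.0)),
            coin_value_gbp=float(d.get("coin_value_gbp", COIN_VALUE_GBP)),
        )


GLOBAL_ONLY = ConditionSpec(
    name="global_only",
    allowed_actions=(Action.INVEST_GLOBAL, Action.KEEP),
    payoff_local=None,
)
BALANCED = ConditionSpec(name="balanced", allowed_actions=tuple(Action))
GLOBAL_BOOST = ConditionSpec(
    name="global_boost", allowed_actions=tuple(Action), payoff_global=2.5
)

CONDITIONS: dict[str, ConditionSpec] = {
    c.name: c for c in (GLOBAL_ONLY, BALANCED, GLOBAL_BOOST)
}


@dataclass(frozen=True)
class ActionProfile:
    """The six simultaneous actions of one round."""

    actions: tuple[Action, ...]
    structure: GroupStructure = DEFAULT_STRUCTURE

    def __post_init__(self) -> None:
        if len(self.actions) != N_PLAYERS:
            raise GameError(f"profile must have {N_PLAYERS} actions, got {len(self.actions)}")

    def validate(self, cond: ConditionSpec) -> None:
        for i, a in enumerate(self.actions):
            cond.validate_action(i, a)

    def replace(self, player: int, action: Action) -> "ActionProfile":
        acts = list(self.actions)
        acts[player] = action
        return ActionProfile(tuple(acts), self.structure)


@dataclass(frozen=True)
class PotTotals:
    """Coin counts per destination after one round; they always sum to 6."""

    global_pot: int
    local_pot_1: int
    local_pot_2: int
    kept: int

    def __post_init__(self) -> None:
        total = self.global_pot + self.local_pot_1 + self.local_pot_2 + self.kept
        if total != N_PLAYERS:
            raise GameError(f"pots must sum to {N_PLAYERS}, got {total}")

    def local_pot(self, subgroup: int) -> int:
        return self.local_pot_1 if subgroup == 1 else self.local_pot_2

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.global_pot, self.local_pot_1, self.local_pot_2, self.kept)


@dataclass(frozen=True)
class ThresholdFlags:
    global_met: bool
    local_1_met: bool
    local_2_met: bool

    def own_local_met(self, subgroup: int) -> bool:
        return self.local_1_met if subgroup == 1 else self.local_2_met


@dataclass(frozen=True)
class RoundOutcome:
    """Pots, threshold flags and the six per-player payoffs of one round."""

    pots: PotTotals
    flags: ThresholdFlags
    payoffs: tuple[float, ...]


def pot_totals(profile: ActionProfile, cond: ConditionSpec) -> PotTotals:
    """Credit each player's coin to exactly one pot.

    An ``invest_other_local`` coin is credited to the *other* subgroup's pot:
    a subgroup-1 member's cross-investment lands in local pot 2 and vice
    versa, and it counts toward that pot's threshold like any other coin.
    """
    profile.validate(cond)
    g = l1 = l2 = kept = 0
    for player, action in enumerate(profile.actions):
        if action is Action.INVEST_GLOBAL:
            g += 1
        elif action is Action.KEEP:
            kept += 1
        else:
            if action is Action.INVEST_OWN_LOCAL:
                target = profile.structure.subgroup_of[player]
            else:
                target = profile.structure.other_subgroup(player)
            if target == 1:
                l1 += 1
            else:
                l2 += 1
    return PotTotals(g, l1, l2, kept)


def thresholds_met(pots: PotTotals, cond: ConditionSpec) -> ThresholdFlags:
    """Compare each pot with its threshold; local flags are always false in
    a condition without local investment (no coin can reach those pots)."""
    local1 = cond.has_local and pots.local_pot_1 >= cond.local_threshold
    local2 = cond.has_local and pots.local_pot_2 >= cond.local_threshold
    return ThresholdFlags(
        global_met=pots.global_pot >= cond.global_threshold,
        local_1_met=local1,
        local_2_met=local2,
    )


def player_payoff(player: int, profile: ActionProfile, cond: ConditionSpec) -> float:
    """One player's total coins for the round.

    Group payoffs go to every member of the rewarded group regardless of the
    member's own action; investing in the other subgroup's pot never pays the
    investor anything.
    """
    pots = pot_totals(profile, cond)
    flags = thresholds_met(pots, cond)
    payoff = 0.0
    if flags.global_met:
        payoff += cond.payoff_global
    if cond.has_local and flags.own_local_met(profile.structure.subgroup_of[player]):
        payoff += cond.payoff_local
    if profile.actions[player] is Action.KEEP:
        payoff += cond.payoff_keep
    return payoff


def round_outcome(profile: ActionProfile, cond: ConditionSpec) -> RoundOutcome:
    """Pots, flags, and all six payoffs for one profile."""
    pots = pot_totals(profile, cond)
    flags = thresholds_met(pots, cond)
    payoffs = []
    for player in range(N_PLAYERS):
        payoff = 0.0
        if flags.global_met:
            payoff += cond.payoff_global
        if cond.has_local and flags.own_local_met(profile.structure.subgroup_of[player]):
            payoff += cond.payoff_local
        if profile.actions[player] is Action.KEEP:
            payoff += cond.payoff_keep
        payoffs.append(payoff)
    return RoundOutcome(pots=pots, flags=flags, payoffs=tuple(payoffs))


def coins_to_gbp(coins: float, cond: ConditionSpec = BALANCED) -> float:
    """Convert coins to pounds sterling at the condition's rate."""
    if coins < 0:
        raise GameError(f"coin amount must be non-negative, got {coins}")
    return coins * cond.coin_value_gbp


def gbp_to_coins(gbp: float, cond: ConditionSpec = BALANCED) -> float:
    """Inverse of :func:`coins_to_gbp`."""
    if gbp < 0:
        raise GameError(f"currency amount must be non-negative, got {gbp}")
    return gbp / cond.coin_value_gbp
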