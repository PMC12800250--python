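"""Exhaustive pure-strategy Nash enumeration for the multilevel game.

The game is small enough to solve by brute force: 2^6 labelled profiles in
the global-only condition and 4^6 otherwise. A labelled profile is a pure
Nash equilibrium when no single player can *strictly* increase their own
payoff by switching to another allowed action while everyone else stands
still. Equilibrium profiles are collapsed to the summary (G, L1, L2, D) —
global investors, coins in each local pot, keepers — which groups the
labelled equilibria into the coordination classes of interest: minimal
winning coalitions at one or both levels, plus full defection.

Mixed-strategy equilibria exist in this game but are out of scope here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .game import (
    N_PLAYERS,
    Action,
    ActionProfile,
    ConditionSpec,
    DEFAULT_STRUCTURE,
    GroupStructure,
    player_payoff,
    pot_totals,
)

ProfileSummary = tuple[int, int, int, int]


def collapse(profile: ActionProfile, cond: ConditionSpec) -> ProfileSummary:
    """Collapse a labelled profile to (G, L1, L2, D).

    L1 and L2 count coins credited to each local pot, so a cross-subgroup
    investment contributes to the other subgroup's component.
    """
    pots = pot_totals(profile, cond)
    return pots.as_tuple()


def unilateral_deviations(
    profile: ActionProfile, player: int, cond: ConditionSpec
) -> list[ActionProfile]:
    """All profiles reachable by changing only ``player``'s action."""
    return [
        profile.replace(player, a)
        for a in cond.allowed_actions
        if a is not profile.actions[player]
    ]


def is_pure_nash(profile: ActionProfile, cond: ConditionSpec) -> bool:
    """True when no player has a strictly profitable unilateral deviation."""
    for player in range(N_PLAYERS):
        current = player_payoff(player, profile, cond)
        for deviation in unilateral_deviations(profile, player, cond):
            if player_payoff(player, deviation, cond) > current:
                return False
    return True


@dataclass(frozen=True)
class EquilibriumReport:
    """All pure equilibria of one condition, labelled and collapsed."""

    condition: str
    profiles: tuple[ActionProfile, ...]
    classes: tuple[ProfileSummary, ...]  # lexicographic descending (G, L1, L2)
    class_counts: dict[ProfileSummary, int]
    n_labelled_profiles: int

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "classes": [list(c) for c in self.classes],
            "class_counts": {str(list(c)): n for c, n in self.class_counts.items()},
            "n_labelled_profiles": self.n_labelled_profiles,
        }


def enumerate_pure_nash(
    cond: ConditionSpec, structure: GroupStructure = DEFAULT_STRUCTURE
) -> EquilibriumReport:
    """Check every labelled action profile of the condition.

    Enumeration runs over labelled players rather than summary classes
    because a summary can be realised by several subgroup compositions and
    the deviation check depends on who, exactly, holds each action.
    """
    equilibria: list[ActionProfile] = []
    counts: dict[ProfileSummary, int] = {}
    n_total = 0
    for actions in itertools.product(cond.allowed_actions, repeat=N_PLAYERS):
        n_total += 1
        profile = ActionProfile(actions, structure)
        if is_pure_nash(profile, cond):
            equilibria.append(profile)
            summary = collapse(profile, cond)
            counts[summary] = counts.get(summary, 0) + 1
    classes = tuple(sorted(counts, key=lambda c: (c[0], c[1], c[2]), reverse=True))
    return EquilibriumReport(
        condition=cond.name,
        profiles=tuple(equilibria),
        classes=classes,
        class_counts=counts,
        n_labelled_profiles=n_total,
    )
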