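"""Fault-assignment strategies: which defectors are punishable.

The community's only lever is the rule deciding which defectors are "at
fault", i.e. liable to receive punishment.  Three rules are implemented:

uniform
    Every defector is at fault (punishment spread over all of them).
single_file
    Defector ``i`` is at fault only if her immediate predecessor ``i-1``
    currently cooperates; player 1 is always at fault when defecting (the
    bootstrap that sets the cascade off).
groups
    Players are partitioned into contiguous blocks of size ``nu`` in the
    published ordering.  A defector in group ``m`` is at fault iff at least a
    proportion ``theta`` of group ``m-1`` cooperates; group 1 is always at
    fault when defecting.

``single_file`` coincides with ``groups`` at ``nu=1`` for any ``theta`` in
(0, 1].  Cooperators are assessed *counterfactually*: a cooperator's deterrent
is the punishment she would attract were she alone to defect, all other
players held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StrategyRule",
    "GroupPartition",
    "FaultAssessment",
    "assign_groups",
    "fault_mask",
    "counterfactual_fault",
]

_KINDS = ("uniform", "single_file", "groups")


@dataclass(frozen=True)
class StrategyRule:
    """A fault-assignment rule.

    ``group_size`` (ν) and ``threshold`` (θ) only matter for ``kind="groups"``.
    """

    kind: str = "uniform"
    group_size: int = 1
    threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown strategy kind {self.kind!r}; expected one of {_KINDS}")
        if self.kind == "groups":
            if self.group_size < 1:
                raise ValueError("group size must be a positive integer")
            if not 0.0 < self.threshold <= 1.0:
                raise ValueError("threshold must lie in (0, 1]")


@dataclass(frozen=True)
class GroupPartition:
    """Contiguous partition of players ``1..N`` into ordered groups.

    ``group_of[k]`` is the 0-based group index of player ``k+1``; ``sizes[m]``
    the number of players in group ``m``.  Only the last group may be short.
    """

    group_of: np.ndarray
    sizes: np.ndarray

    @property
    def n_groups(self) -> int:
        return int(self.sizes.size)

    @property
    def n_players(self) -> int:
        return int(self.group_of.size)

    def members(self, m: int) -> np.ndarray:
        """1-based player indices of group ``m`` (0-based)."""
        return np.flatnonzero(self.group_of == m) + 1


@dataclass(frozen=True)
class FaultAssessment:
    """Boolean at-fault mask over players plus the at-fault count ``n_f``."""

    at_fault: np.ndarray
    n_f: int = field(default=-1)

    def __post_init__(self) -> None:
        object.__setattr__(self, "at_fault", np.asarray(self.at_fault, dtype=bool))
        if self.n_f < 0:
            object.__setattr__(self, "n_f", int(self.at_fault.sum()))


def assign_groups(n_players: int, group_size: int) -> GroupPartition:
    """Partition ``1..N`` into ``ceil(N/ν)`` contiguous groups of size ``ν``."""
    if not 1 <= group_size <= n_players:
        raise ValueError(
            f"group size must lie in 1..{n_players}, got {group_size}"
        )
    group_of = np.arange(n_players) // group_size
    sizes = np.bincount(group_of)
    return GroupPartition(group_of=group_of, sizes=sizes)


def _partition_for(rule: StrategyRule, n: int, partition: GroupPartition | None) -> GroupPartition | None:
    if rule.kind != "groups":
        return None
    if partition is None:
        return assign_groups(n, rule.group_size)
    if partition.n_players != n:
        raise ValueError("partition size does not match state length")
    return partition


def fault_mask(
    cooperates: np.ndarray,
    rule: StrategyRule,
    partition: GroupPartition | None = None,
) -> FaultAssessment:
    """At-fault mask of a configuration under ``rule``.

    Parameters
    ----------
    cooperates
        Boolean state per player, ``True`` meaning cooperate, position ``k``
        holding player ``k+1``.
    partition
        Precomputed group partition (``groups`` rule only); built from
        ``rule.group_size`` when omitted.
    """
    c = np.asarray(cooperates, dtype=bool)
    defects = ~c
    if rule.kind == "uniform":
        return FaultAssessment(defects)
    if rule.kind == "single_file":
        # predecessor cooperates; player 1's "predecessor" is the bootstrap
        pred_ok = np.empty_like(c)
        pred_ok[0] = True
        pred_ok[1:] = c[:-1]
        return FaultAssessment(defects & pred_ok)
    part = _partition_for(rule, c.size, partition)
    counts = np.bincount(part.group_of, weights=c, minlength=part.n_groups)
    group_ok = np.empty(part.n_groups, dtype=bool)
    group_ok[0] = True
    # "at least a proportion θ" of the actual size of the previous group
    group_ok[1:] = counts[:-1] >= rule.threshold * part.sizes[:-1]
    return FaultAssessment(defects & group_ok[part.group_of])


def counterfactual_fault(
    cooperates: np.ndarray,
    rule: StrategyRule,
    partition: GroupPartition | None,
    player: int,
) -> FaultAssessment:
    """Fault assessment if cooperator ``player`` (1-based) alone defected.

    All other players are held at their current states.  The returned mask is
    over the flipped configuration, so it reports both whether ``player``
    herself would be at fault and the counterfactual at-fault count ``ñ_f``.
    """
    c = np.asarray(cooperates, dtype=bool)
    if not 1 <= player <= c.size:
        raise IndexError(f"player index {player} outside 1..{c.size}")
    if not c[player - 1]:
        raise ValueError(f"player {player} already defects; counterfactual undefined")
    flipped = c.copy()
    flipped[player - 1] = False
    return fault_mask(flipped, rule, partition)
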