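"""Stochastic dynamics of the punishment game.

Each player ``i`` perceives a payoff balance ``H_i = p_i + h_i``: her intrinsic
predisposition ``h_i`` plus the punishment pressure ``p_i`` bearing on her.
At every (synchronous) time step she cooperates with probability

    P_i = (1/2) * [tanh(beta * H_i) + 1],

the Glauber/logit choice rule: ``beta = 0`` is a fair coin, ``beta -> inf`` the
deterministic best response (``P = 1/2`` exactly at ``H = 0``).

Punishment pressure.  ``n_p`` punishers each wield capacity ``pi``, divided
equally over the ``n_f`` players currently at fault, so a defector at fault
receives ``p = pi * n_p / n_f``; a defector not at fault receives nothing.  A
cooperator is deterred counterfactually: if she would be at fault were she
alone to defect, ``p = pi * ñ_p / ñ_f`` with the punisher and fault counts of
that one-flip configuration (she would not punish herself, so under the
cooperators pool ``ñ_p = n_c - 1``); otherwise ``p = 0``.

Punisher pools: ``"cooperators"`` (``n_p = n_c``, the default), ``"all"``
(``n_p = N``: defectors punish too), and ``"fraction"`` (``n_p = a * n_c``,
equivalent to rescaling ``pi -> a * pi``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fault_rules import (
    FaultAssessment,
    GroupPartition,
    StrategyRule,
    assign_groups,
    counterfactual_fault,
    fault_mask,
)
from .population import PredispositionProfile

__all__ = [
    "DynamicsParams",
    "StateVector",
    "InfluenceBreakdown",
    "SimulationConfig",
    "Trajectory",
    "StationaryEstimate",
    "SpeedResult",
    "effective_punishers",
    "influence",
    "cooperation_probabilities",
    "step",
    "run_trajectory",
    "estimate_stationary",
    "time_to_cooperation",
]

_POOLS = ("cooperators", "all", "fraction")


@dataclass(frozen=True)
class DynamicsParams:
    """Rationality ``beta``, punishment capacity ``pi_cap`` and punisher pool.

    ``beta`` may be ``math.inf`` for the deterministic limit (threshold rule).
    ``punishing_fraction`` (a) is used only with ``pool="fraction"``.
    """

    beta: float = 1.0
    pi_cap: float = 0.0
    pool: str = "cooperators"
    punishing_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.pi_cap < 0:
            raise ValueError("punishment capacity must be non-negative")
        if self.pool not in _POOLS:
            raise ValueError(f"unknown pool {self.pool!r}; expected one of {_POOLS}")
        if not 0.0 < self.punishing_fraction <= 1.0:
            raise ValueError("punishing fraction must lie in (0, 1]")

    @property
    def deterministic(self) -> bool:
        return math.isinf(self.beta)


@dataclass(frozen=True)
class StateVector:
    """Boolean population state; ``True`` = cooperate."""

    states: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", np.asarray(self.states, dtype=bool))

    @property
    def n_players(self) -> int:
        return int(self.states.size)

    @property
    def n_cooperators(self) -> int:
        return int(self.states.sum())

    @property
    def rho(self) -> float:
        return self.n_cooperators / self.n_players

    @classmethod
    def all_cooperate(cls, n: int) -> "StateVector":
        return cls(np.ones(n, dtype=bool))

    @classmethod
    def all_defect(cls, n: int) -> "StateVector":
        return cls(np.zeros(n, dtype=bool))


@dataclass(frozen=True)
class InfluenceBreakdown:
    """One player's decision terms: ``p``, ``h``, ``H = p + h``, ``P`` and the
    punisher/fault counts (counterfactual ones for a cooperator)."""

    p: float
    h: float
    balance: float
    prob_cooperate: float
    n_p: float
    n_f: int


def effective_punishers(state: StateVector, pool: str, punishing_fraction: float = 1.0) -> float:
    """Number of punishers ``n_p`` under the given pool policy."""
    if pool == "cooperators":
        return float(state.n_cooperators)
    if pool == "all":
        return float(state.n_players)
    if pool == "fraction":
        return punishing_fraction * state.n_cooperators
    raise ValueError(f"unknown pool {pool!r}; expected one of {_POOLS}")


def _sigmoid(balance: np.ndarray | float, beta: float) -> np.ndarray | float:
    if math.isinf(beta):
        return np.where(
            np.asarray(balance) > 0, 1.0, np.where(np.asarray(balance) < 0, 0.0, 0.5)
        )
    return 0.5 * (np.tanh(beta * np.asarray(balance)) + 1.0)


def influence(
    player: int,
    state: StateVector,
    profile: PredispositionProfile,
    rule: StrategyRule,
    params: DynamicsParams,
    partition: GroupPartition | None = None,
) -> InfluenceBreakdown:
    """Decision terms of one player (1-based), straight from the definitions.

    This is the reference (per-player) route; :func:`cooperation_probabilities`
    is the vectorized route used by the simulator, and the two are held to
    agree by the test suite.
    """
    c = state.states
    n = c.size
    if not 1 <= player <= n:
        raise IndexError(f"player index {player} outside 1..{n}")
    h = profile.h(player)
    if c[player - 1]:
        cf = counterfactual_fault(c, rule, partition, player)
        if cf.at_fault[player - 1]:
            counter = StateVector(np.delete(c, player - 1))  # she is not her own punisher
            if params.pool == "all":
                n_p = float(n)
            else:
                n_p = effective_punishers(counter, params.pool, params.punishing_fraction)
            p = params.pi_cap * n_p / cf.n_f
            n_f = cf.n_f
        else:
            p, n_p, n_f = 0.0, 0.0, 0
    else:
        fa = fault_mask(c, rule, partition)
        if fa.at_fault[player - 1]:
            n_p = effective_punishers(state, params.pool, params.punishing_fraction)
            if fa.n_f == 0:
                raise RuntimeError("at-fault player with n_f = 0; inconsistent mask")
            p = params.pi_cap * n_p / fa.n_f
            n_f = fa.n_f
        else:
            p, n_p, n_f = 0.0, 0.0, 0
    balance = p + h
    return InfluenceBreakdown(
        p=p,
        h=h,
        balance=balance,
        prob_cooperate=float(_sigmoid(balance, params.beta)),
        n_p=n_p,
        n_f=n_f,
    )


def _counterfactual_all(
    c: np.ndarray,
    rule: StrategyRule,
    partition: GroupPartition | None,
    assessment: FaultAssessment,
) -> tuple[np.ndarray, np.ndarray]:
    """Counterfactual own-fault flag and at-fault count ``ñ_f`` for every player.

    Entry ``k`` answers: if player ``k+1`` (assumed cooperating) alone
    defected, would she be at fault, and how many players would be at fault?
    Entries for players currently defecting are meaningless and must be
    ignored by the caller.  O(N) for every rule — equivalent to N one-flip
    calls of :func:`fault_mask` but without the N^2 cost.
    """
    n = c.size
    n_f = assessment.n_f
    if rule.kind == "uniform":
        own = np.ones(n, dtype=bool)
        nf_tilde = np.full(n, n_f + 1)
        return own, nf_tilde
    if rule.kind == "single_file":
        own = np.empty(n, dtype=bool)
        own[0] = True
        own[1:] = c[:-1]
        # flipping k removes the fault of a defecting successor (whose
        # predecessor k currently cooperates, so it was at fault)
        succ_defects = np.zeros(n, dtype=bool)
        succ_defects[:-1] = ~c[1:]
        return own, n_f + own.astype(int) - succ_defects.astype(int)
    part = partition if partition is not None else assign_groups(n, rule.group_size)
    counts = np.bincount(part.group_of, weights=c, minlength=part.n_groups)
    defect_counts = part.sizes - counts
    group_ok = np.empty(part.n_groups, dtype=bool)
    group_ok[0] = True
    group_ok[1:] = counts[:-1] >= rule.threshold * part.sizes[:-1]
    own = group_ok[part.group_of]
    # one fewer cooperator in group g may disable the fault of group g+1
    thresh = rule.threshold * part.sizes
    disables = (counts >= thresh) & (counts - 1 < thresh)
    delta = np.zeros(part.n_groups)
    delta[:-1] = np.where(disables[:-1], defect_counts[1:], 0.0)
    return own, n_f + own.astype(int) - delta[part.group_of].astype(int)


def cooperation_probabilities(
    state: StateVector,
    profile: PredispositionProfile,
    rule: StrategyRule,
    params: DynamicsParams,
    partition: GroupPartition | None = None,
) -> np.ndarray:
    """Vector of next-step cooperation probabilities ``P_i`` for all players."""
    c = state.states
    n = c.size
    if profile.n_players != n:
        raise ValueError("profile and state lengths differ")
    fa = fault_mask(c, rule, partition)
    p = np.zeros(n)
    if params.pi_cap > 0:
        n_c = int(c.sum())
        if params.pool == "cooperators":
            n_p, np_tilde = float(n_c), float(n_c - 1)
        elif params.pool == "all":
            n_p = np_tilde = float(n)
        else:
            a = params.punishing_fraction
            n_p, np_tilde = a * n_c, a * (n_c - 1)
        if fa.n_f > 0:
            p[fa.at_fault] = params.pi_cap * n_p / fa.n_f
        own, nf_tilde = _counterfactual_all(c, rule, partition, fa)
        coop_punished = c & own
        p[coop_punished] = params.pi_cap * np_tilde / nf_tilde[coop_punished]
    return np.asarray(_sigmoid(p + profile.values, params.beta), dtype=float)


def step(
    state: StateVector,
    profile: PredispositionProfile,
    rule: StrategyRule,
    params: DynamicsParams,
    rng: np.random.Generator,
    partition: GroupPartition | None = None,
) -> StateVector:
    """One synchronous update: every player redrawn from the time-t configuration."""
    probs = cooperation_probabilities(state, profile, rule, params, partition)
    return StateVector(rng.random(state.n_players) < probs)


def step_async(
    state: StateVector,
    profile: PredispositionProfile,
    rule: StrategyRule,
    params: DynamicsParams,
    rng: np.random.Generator,
    partition: GroupPartition | None = None,
) -> StateVector:
    """One asynchronous tick: a single uniformly chosen player is redrawn."""
    i = int(rng.integers(state.n_players)) + 1
    b = influence(i, state, profile, rule, params, partition)
    new = state.states.copy()
    new[i - 1] = rng.random() < b.prob_cooperate
    return StateVector(new)


@dataclass(frozen=True)
class SimulationConfig:
    """Run lengths, replication, initial condition and seeding.

    ``init`` is ``"all_C"``, ``"all_D"``, a float in [0, 1] (each player
    independently cooperates with that probability at t=0) or an explicit
    boolean array.  ``update`` selects synchronous (default) or asynchronous
    stepping.
    """

    t_max: int = 2000
    burn_in: int = 500
    window: int = 500
    realizations: int = 100
    init: object = "all_D"
    seed: int = 0
    update: str = "synchronous"
    record_states: bool = False

    def __post_init__(self) -> None:
        if self.t_max < 0 or self.burn_in < 0 or self.window < 0:
            raise ValueError("t_max, burn_in and window must be non-negative")
        if self.burn_in + self.window > self.t_max:
            raise ValueError("burn_in + window must not exceed t_max")
        if self.realizations < 1:
            raise ValueError("need at least one realization")
        if self.update not in ("synchronous", "asynchronous"):
            raise ValueError("update must be 'synchronous' or 'asynchronous'")

    def initial_state(self, n: int, rng: np.random.Generator) -> StateVector:
        if isinstance(self.init, str):
            if self.init == "all_C":
                return StateVector.all_cooperate(n)
            if self.init == "all_D":
                return StateVector.all_defect(n)
            raise ValueError(f"unknown init {self.init!r}")
        if isinstance(self.init, (int, float)) and not isinstance(self.init, bool):
            dens = float(self.init)
            if not 0.0 <= dens <= 1.0:
                raise ValueError("initial density must lie in [0, 1]")
            return StateVector(rng.random(n) < dens)
        arr = np.asarray(self.init, dtype=bool)
        if arr.size != n:
            raise ValueError("explicit initial state has wrong length")
        return StateVector(arr)


@dataclass(frozen=True)
class Trajectory:
    """Densities ``rho_t`` for ``t = 0..T`` (and optionally the full states)."""

    rho: np.ndarray
    states: np.ndarray | None = None

    @property
    def n_steps(self) -> int:
        return int(self.rho.size - 1)


@dataclass(frozen=True)
class StationaryEstimate:
    """Stationary density: mean over the averaging window, across realizations."""

    rho_mean: float
    se: float
    per_realization: np.ndarray


@dataclass(frozen=True)
class SpeedResult:
    """First-passage times to full cooperation and speeds ``v = N/tau``.

    ``tau`` is the first ``t >= 1`` with every player cooperating (0 when the
    initial state already is fully cooperative, for which ``v`` is undefined);
    censored runs (never fully cooperative within ``t_max``) carry ``tau = -1``.
    """

    tau: np.ndarray
    n_players: int
    t_max: int

    @property
    def censored(self) -> np.ndarray:
        return self.tau < 0

    @property
    def censored_fraction(self) -> float:
        return float(self.censored.mean())

    @property
    def speeds(self) -> np.ndarray:
        """``v = N/tau`` of the uncensored runs with ``tau >= 1``."""
        ok = (~self.censored) & (self.tau >= 1)
        return self.n_players / self.tau[ok]

    @property
    def mean_speed(self) -> float:
        """Mean speed over valid runs; 0.0 when every run is censored."""
        v = self.speeds
        return float(v.mean()) if v.size else 0.0


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _stepper(config: SimulationConfig):
    return step if config.update == "synchronous" else step_async


def run_trajectory(
    config: SimulationConfig,
    profile: PredispositionProfile,
    rule: StrategyRule,
    params: DynamicsParams,
    rng: np.random.Generator | None = None,
    n_steps: int | None = None,
) -> Trajectory:
    """Simulate one realization for ``n_steps`` (default ``t_max``) steps."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = profile.n_players
    part = assign_groups(n, rule.group_size) if rule.kind == "groups" else None
    advance = _stepper(config)
    steps = config.t_max if n_steps is None else n_steps
    state = config.initial_state(n, rng)
    rho = np.empty(steps + 1)
    rho[0] = state.rho
    history = [state.states.copy()] if config.record_states else None
    for t in range(1, steps + 1):
        state = advance(state, profile, rule, params, rng, part)
        rho[t] = state.rho
        if history is not None:
            history.append(state.states.copy())
    return Trajectory(rho=rho, states=np.array(history) if history is not None else None)


def estimate_stationary(
    config: SimulationConfig,
    profile: PredispositionProfile,
    rule: StrategyRule,
    params: DynamicsParams,
) -> StationaryEstimate:
    """Stationary density: per realization, ``rho_t`` averaged over the window
    after burn-in; mean and standard error across realizations.

    Only ``burn_in + window`` steps are simulated per realization (``t_max``
    is a cap, not a demand).  Realizations use independent substreams spawned
    deterministically from ``config.seed``.
    """
    if config.window == 0:
        raise ValueError("averaging window must be positive")
    steps = config.burn_in + config.window
    means = np.empty(config.realizations)
    for r, rng in enumerate(_substreams(config.seed, config.realizations)):
        traj = run_trajectory(config, profile, rule, params, rng=rng, n_steps=steps)
        means[r] = traj.rho[config.burn_in + 1 :].mean()
    se = means.std(ddof=1) / math.sqrt(len(means)) if len(means) > 1 else 0.0
    return StationaryEstimate(rho_mean=float(means.mean()), se=float(se), per_realization=means)


def time_to_cooperation(
    config: SimulationConfig,
    profile: PredispositionProfile,
    rule: StrategyRule,
    params: DynamicsParams,
) -> SpeedResult:
    """First-passage time to full cooperation per realization, censored at ``t_max``."""
    n = profile.n_players
    part = assign_groups(n, rule.group_size) if rule.kind == "groups" else None
    advance = _stepper(config)
    taus = np.empty(config.realizations, dtype=np.int64)
    for r, rng in enumerate(_substreams(config.seed, config.realizations)):
        state = config.initial_state(n, rng)
        if state.n_cooperators == n:
            taus[r] = 0
            continue
        taus[r] = -1
        for t in range(1, config.t_max + 1):
            state = advance(state, profile, rule, params, rng, part)
            if state.n_cooperators == n:
                taus[r] = t
                break
    return SpeedResult(tau=taus, n_players=n, t_max=config.t_max)


def time_to_density(
    config: SimulationConfig,
    profile: PredispositionProfile,
    rule: StrategyRule,
    params: DynamicsParams,
    threshold: float,
) -> SpeedResult:
    """Variant first-passage time: first ``t >= 1`` with ``rho_t >= threshold``.

    Useful at moderate ``beta`` where exact unanimity is repeatedly broken by
    single-player fluctuations.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    n = profile.n_players
    part = assign_groups(n, rule.group_size) if rule.kind == "groups" else None
    advance = _stepper(config)
    taus = np.empty(config.realizations, dtype=np.int64)
    for r, rng in enumerate(_substreams(config.seed, config.realizations)):
        state = config.initial_state(n, rng)
        if state.rho >= threshold:
            taus[r] = 0
            continue
        taus[r] = -1
        for t in range(1, config.t_max + 1):
            state = advance(state, profile, rule, params, rng, part)
            if state.rho >= threshold:
                taus[r] = t
                break
    return SpeedResult(tau=taus, n_players=n, t_max=config.t_max)
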