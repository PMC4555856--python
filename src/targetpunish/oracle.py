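"""Exact finite-chain reference solution.

The synchronous dynamics on ``N`` players is a Markov chain on the ``2^N``
binary configurations whose transition kernel factorizes over players:

    T[s -> s'] = prod_i ( P_i(s) if s'_i = C else 1 - P_i(s) ),

with ``P_i(s)`` the per-player cooperation probabilities of the simulator.
For small populations the chain can be built densely and its stationary
distribution obtained by power iteration, giving exact long-run expectations
against which Monte-Carlo estimates are validated.  Finite ``beta`` makes
every transition probability strictly positive, so the chain is ergodic and
the stationary law unique; the deterministic limit (``beta = inf``) is
excluded because the chain may then be reducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import DynamicsParams, StateVector, cooperation_probabilities
from .fault_rules import StrategyRule, assign_groups
from .population import PredispositionProfile

__all__ = ["ExactChain", "build_chain", "stationary_distribution", "expected_density"]

MAX_PLAYERS = 12


@dataclass(frozen=True)
class ExactChain:
    """Dense synchronous-update chain over all ``2^N`` configurations.

    ``configs[s]`` is the boolean configuration with index ``s`` (player ``i``
    cooperates iff bit ``i-1`` of ``s`` is set); ``transition`` is the
    row-stochastic ``2^N x 2^N`` kernel.
    """

    n_players: int
    configs: np.ndarray
    transition: np.ndarray

    @property
    def n_states(self) -> int:
        return int(self.configs.shape[0])

    @property
    def densities(self) -> np.ndarray:
        """Cooperator density of each configuration."""
        return self.configs.sum(axis=1) / self.n_players


def build_chain(
    profile: PredispositionProfile,
    rule: StrategyRule,
    params: DynamicsParams,
) -> ExactChain:
    """Construct the full transition matrix (``N <= 12``, finite ``beta``)."""
    n = profile.n_players
    if n > MAX_PLAYERS:
        raise ValueError(f"exact chain limited to N <= {MAX_PLAYERS}, got {n}")
    if math.isinf(params.beta):
        raise ValueError("deterministic limit not supported by the exact chain")
    part = assign_groups(n, rule.group_size) if rule.kind == "groups" else None
    n_states = 1 << n
    idx = np.arange(n_states)
    configs = ((idx[:, None] >> np.arange(n)[None, :]) & 1).astype(bool)
    probs = np.empty((n_states, n))
    for s in range(n_states):
        probs[s] = cooperation_probabilities(
            StateVector(configs[s]), profile, rule, params, part
        )
    transition = np.ones((n_states, n_states))
    for i in range(n):
        coop_next = configs[:, i]
        transition *= np.where(coop_next[None, :], probs[:, i : i + 1], 1.0 - probs[:, i : i + 1])
    return ExactChain(n_players=n, configs=configs, transition=transition)


def stationary_distribution(
    chain: ExactChain,
    tol: float = 1e-12,
    max_iter: int = 1_000_000,
    start: np.ndarray | None = None,
) -> np.ndarray:
    """Stationary law by power iteration to L1 change below ``tol``."""
    v = (
        np.full(chain.n_states, 1.0 / chain.n_states)
        if start is None
        else np.asarray(start, dtype=float) / np.asarray(start, dtype=float).sum()
    )
    for _ in range(max_iter):
        nxt = v @ chain.transition
        nxt /= nxt.sum()
        if np.abs(nxt - v).sum() < tol:
            return nxt
        v = nxt
    raise RuntimeError(f"power iteration did not converge within {max_iter} iterations")


def expected_density(chain: ExactChain, stationary: np.ndarray | None = None) -> float:
    """Stationary expectation of the cooperator density ``rho``."""
    if stationary is None:
        stationary = stationary_distribution(chain)
    return float(stationary @ chain.densities)
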