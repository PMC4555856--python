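"""Heterogeneous predisposition profiles.

Each of the ``N`` players carries an intrinsic predisposition ``h_i`` — the net
payoff difference she perceives between cooperating and defecting before any
punishment is applied.  Players are indexed ``i = 1..N`` from most to least
inherently cooperative.  The baseline profile is linear in rank,

    h_i = -(i - 2) / (N - 2),

so the first player has a slight tendency to cooperate (``h_1 = 1/(N-2)``),
the second is indifferent (``h_2 = 0``) and the last is maximally predisposed
to defect (``h_N = -1``).

Three perturbations probe the robustness of punishment strategies to imperfect
knowledge of the ordering: rescaling the spread of ``h`` about its mean,
additive Gaussian noise, and random transpositions of a fraction of players.
Perturbed values keep their positions — strategies always act on the published
ordering ``1..N``, not on a re-sorted one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PredispositionProfile",
    "PerturbationSpec",
    "build_linear_profile",
    "scale_heterogeneity",
    "apply_gaussian_noise",
    "swap_positions",
    "read_profile",
    "write_profile",
]


@dataclass(frozen=True)
class PredispositionProfile:
    """Ordered intrinsic cooperation tendencies ``h_1..h_N``.

    Parameters
    ----------
    values
        Predisposition of each player, position ``k`` (0-based) holding player
        ``i = k + 1``'s value.  Dimensionless payoff units.
    provenance
        ``"baseline"`` for the exact linear profile, ``"perturbed"`` after any
        modification.
    """

    values: np.ndarray
    provenance: str = "baseline"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("profile values must be a non-empty 1-D sequence")

    @property
    def n_players(self) -> int:
        return int(self.values.size)

    def h(self, i: int) -> float:
        """Predisposition of player ``i`` (1-based, as in the ordering)."""
        if not 1 <= i <= self.n_players:
            raise IndexError(f"player index {i} outside 1..{self.n_players}")
        return float(self.values[i - 1])

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class PerturbationSpec:
    """Composite perturbation: heterogeneity scaling, noise, then swaps.

    ``noise_sd=0``, ``swap_fraction=0`` and ``heterogeneity_scale=1`` together
    are the identity.  The three steps are applied in the order scale → noise →
    swap; independent sub-seeds are derived from ``seed`` so each step is
    individually reproducible.
    """

    noise_sd: float = 0.0
    swap_fraction: float = 0.0
    heterogeneity_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.swap_fraction <= 1.0:
            raise ValueError("swap_fraction must lie in [0, 1]")
        if self.heterogeneity_scale < 0:
            raise ValueError("heterogeneity_scale must be non-negative")

    @property
    def is_identity(self) -> bool:
        return (
            self.noise_sd == 0.0
            and self.swap_fraction == 0.0
            and self.heterogeneity_scale == 1.0
        )

    def apply(self, profile: PredispositionProfile) -> PredispositionProfile:
        if self.is_identity:
            return profile
        noise_seed, swap_seed = np.random.SeedSequence(self.seed).generate_state(2)
        out = scale_heterogeneity(profile, self.heterogeneity_scale)
        out = apply_gaussian_noise(out, self.noise_sd, int(noise_seed))
        return swap_positions(out, self.swap_fraction, int(swap_seed))


def build_linear_profile(n_players: int) -> PredispositionProfile:
    """Baseline linear profile ``h_i = -(i-2)/(N-2)`` for ``i = 1..N``.

    Requires ``N >= 3`` (the formula is degenerate below that).  The result is
    strictly decreasing, with mean ``-(N-3)/(2(N-2))``.
    """
    if n_players < 3:
        raise ValueError(f"need at least 3 players, got {n_players}")
    i = np.arange(1, n_players + 1, dtype=float)
    return PredispositionProfile(-(i - 2.0) / (n_players - 2.0), provenance="baseline")


def scale_heterogeneity(
    profile: PredispositionProfile, scale: float
) -> PredispositionProfile:
    """Rescale the spread of predispositions about their (preserved) mean.

    ``h'_i = m + scale * (h_i - m)`` with ``m`` the profile mean; ``scale=0``
    collapses to a homogeneous population, ``scale=1`` is the identity.
    """
    if scale < 0:
        raise ValueError("heterogeneity scale must be non-negative")
    if scale == 1.0:
        return profile
    m = profile.values.mean()
    return PredispositionProfile(m + scale * (profile.values - m), provenance="perturbed")


def apply_gaussian_noise(
    profile: PredispositionProfile, sd: float, seed: int
) -> PredispositionProfile:
    """Add i.i.d. zero-mean Gaussian deviates of standard deviation ``sd``."""
    if sd < 0:
        raise ValueError("noise standard deviation must be non-negative")
    if sd == 0:
        return profile
    rng = np.random.default_rng(seed)
    noisy = profile.values + rng.normal(0.0, sd, size=profile.n_players)
    return PredispositionProfile(noisy, provenance="perturbed")


def swap_positions(
    profile: PredispositionProfile, fraction: float, seed: int
) -> PredispositionProfile:
    """Transpose ``round(fraction * N)`` randomly chosen players with random counterparts.

    The selected indices are distinct (drawn without replacement); each, in
    selection order, exchanges values with one counterpart drawn uniformly from
    all ``N`` positions (a self-swap is a no-op).  The multiset of values is
    preserved exactly.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("swap fraction must lie in [0, 1]")
    n = profile.n_players
    n_swaps = int(round(fraction * n))
    if n_swaps == 0:
        return profile
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=n_swaps, replace=False)
    partners = rng.integers(0, n, size=n_swaps)
    values = profile.values.copy()
    for a, b in zip(chosen, partners):
        values[a], values[b] = values[b], values[a]
    return PredispositionProfile(values, provenance="perturbed")


def write_profile(profile: PredispositionProfile, path: str | Path) -> None:
    """Write a profile as two-column CSV ``player_index,h`` (1-based indices)."""
    path = Path(path)
    lines = ["player_index,h"]
    lines += [f"{i + 1},{float(v)!r}" for i, v in enumerate(profile.values)]
    path.write_text("\n".join(lines) + "\n")


def read_profile(path: str | Path) -> PredispositionProfile:
    """Read a profile written by :func:`write_profile`."""
    rows = Path(path).read_text().strip().splitlines()
    if not rows or rows[0].split(",")[0] != "player_index":
        raise ValueError(f"{path}: missing 'player_index,h' header")
    pairs = [line.split(",") for line in rows[1:]]
    order = np.argsort([int(p[0]) for p in pairs])
    values = np.array([float(p[1]) for p in pairs])[order]
    return PredispositionProfile(values, provenance="perturbed")
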