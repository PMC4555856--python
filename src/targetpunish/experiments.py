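"""Phase-diagram sweeps, comparisons, speed maps and configuration I/O.

A sweep evaluates the stationary cooperator density (or the speed to full
cooperation) on a grid of (rationality ``beta``, punishment ``pi``) cells,
each cell averaged over independent realizations with a deterministically
derived sub-seed, so any sweep is bit-reproducible from its configuration and
master seed.  Grids are written as long-format CSV plus a JSON metadata
sidecar.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import (
    DynamicsParams,
    SimulationConfig,
    estimate_stationary,
    time_to_cooperation,
)
from .fault_rules import StrategyRule
from .population import PerturbationSpec, PredispositionProfile, build_linear_profile

__all__ = [
    "SweepGrid",
    "SweepComparison",
    "RunConfig",
    "run_sweep",
    "compare_sweeps",
    "speed_map",
    "achievable_fraction",
    "read_run_config",
    "write_run_config",
    "write_grid",
    "read_grid",
]


@dataclass(frozen=True)
class SweepGrid:
    """Matrix of per-cell results over a (beta, pi) grid.

    ``value[b, p]`` is the stationary density (kind="rho") or mean speed
    (kind="speed") at ``beta_values[b]``, ``pi_values[p]``; ``se`` the
    standard error across realizations (NaN where undefined) and
    ``censored_fraction`` the per-cell fraction of runs that never reached
    full cooperation (speed maps only, else NaN).
    """

    beta_values: np.ndarray
    pi_values: np.ndarray
    value: np.ndarray
    se: np.ndarray
    censored_fraction: np.ndarray
    kind: str = "rho"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = (len(self.beta_values), len(self.pi_values))
        if self.value.shape != expected:
            raise ValueError(f"value matrix shape {self.value.shape} != {expected}")


@dataclass(frozen=True)
class SweepComparison:
    """Cellwise difference ``reference - test`` between two grids on one axis set."""

    beta_values: np.ndarray
    pi_values: np.ndarray
    delta: np.ndarray
    metadata: dict = field(default_factory=dict)


def _cell_seed(master_seed: int, b: int, p: int) -> int:
    # deterministic, collision-free sub-seed per cell, below 2^31
    return int(
        np.random.SeedSequence((int(master_seed), int(b), int(p))).generate_state(1)[0]
        % (2**31)
    )


def _rule_metadata(rule: StrategyRule) -> dict:
    return {"strategy": rule.kind, "nu": rule.group_size, "theta": rule.threshold}


def run_sweep(
    beta_values,
    pi_values,
    rule: StrategyRule,
    params_template: DynamicsParams,
    config: SimulationConfig,
    profile: PredispositionProfile,
) -> SweepGrid:
    """Stationary-density grid: :func:`estimate_stationary` per (beta, pi) cell.

    ``params_template`` fixes the pool policy; its ``beta`` and ``pi_cap``
    are overridden cell by cell.
    """
    beta_values = np.asarray(beta_values, dtype=float)
    pi_values = np.asarray(pi_values, dtype=float)
    value = np.empty((beta_values.size, pi_values.size))
    se = np.empty_like(value)
    for b, beta in enumerate(beta_values):
        for p, pi_cap in enumerate(pi_values):
            params = dataclasses.replace(params_template, beta=float(beta), pi_cap=float(pi_cap))
            cell_cfg = dataclasses.replace(config, seed=_cell_seed(config.seed, b, p))
            est = estimate_stationary(cell_cfg, profile, rule, params)
            value[b, p] = est.rho_mean
            se[b, p] = est.se
    meta = {
        "kind": "rho",
        "n_players": profile.n_players,
        "realizations": config.realizations,
        "init": str(config.init),
        "burn_in": config.burn_in,
        "window": config.window,
        "master_seed": config.seed,
        "pool": params_template.pool,
        **_rule_metadata(rule),
    }
    return SweepGrid(
        beta_values=beta_values,
        pi_values=pi_values,
        value=value,
        se=se,
        censored_fraction=np.full_like(value, np.nan),
        kind="rho",
        metadata=meta,
    )


def speed_map(
    beta_values,
    pi_values,
    rule: StrategyRule,
    params_template: DynamicsParams,
    config: SimulationConfig,
    profile: PredispositionProfile,
) -> SweepGrid:
    """Speed grid ``v = N/tau`` from an all-defect start.

    Cells whose runs are all censored (full cooperation never reached within
    ``t_max``) report ``v = 0`` with censored fraction 1.
    """
    if config.init != "all_D":
        raise ValueError("speed maps are defined for the all_D initial condition")
    beta_values = np.asarray(beta_values, dtype=float)
    pi_values = np.asarray(pi_values, dtype=float)
    value = np.empty((beta_values.size, pi_values.size))
    se = np.empty_like(value)
    censored = np.empty_like(value)
    for b, beta in enumerate(beta_values):
        for p, pi_cap in enumerate(pi_values):
            params = dataclasses.replace(params_template, beta=float(beta), pi_cap=float(pi_cap))
            cell_cfg = dataclasses.replace(config, seed=_cell_seed(config.seed, b, p))
            res = time_to_cooperation(cell_cfg, profile, rule, params)
            speeds = res.speeds
            value[b, p] = res.mean_speed
            se[b, p] = (
                speeds.std(ddof=1) / math.sqrt(speeds.size) if speeds.size > 1 else np.nan
            )
            censored[b, p] = res.censored_fraction
    meta = {
        "kind": "speed",
        "n_players": profile.n_players,
        "realizations": config.realizations,
        "init": str(config.init),
        "t_max": config.t_max,
        "master_seed": config.seed,
        "pool": params_template.pool,
        **_rule_metadata(rule),
    }
    return SweepGrid(
        beta_values=beta_values,
        pi_values=pi_values,
        value=value,
        se=se,
        censored_fraction=censored,
        kind="speed",
        metadata=meta,
    )


def compare_sweeps(reference: SweepGrid, test: SweepGrid) -> SweepComparison:
    """Cellwise ``reference - test``; the grids must share both axes."""
    if reference.value.shape != test.value.shape or not (
        np.array_equal(reference.beta_values, test.beta_values)
        and np.array_equal(reference.pi_values, test.pi_values)
    ):
        raise ValueError("sweep grids have mismatching axes")
    return SweepComparison(
        beta_values=reference.beta_values,
        pi_values=reference.pi_values,
        delta=reference.value - test.value,
        metadata={"reference": reference.metadata, "test": test.metadata},
    )


def achievable_fraction(grid: SweepGrid, threshold: float = 0.9) -> float:
    """Fraction of grid cells whose stationary density reaches ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    return float((grid.value >= threshold).mean())


# --------------------------------------------------------------------------
# run configuration (YAML)

_INITS = ("all_C", "all_D")


@dataclass(frozen=True)
class RunConfig:
    """Complete experiment configuration with the package defaults filled in.

    ``init`` is ``"all_C"``, ``"all_D"`` or ``"density:<x>"``.
    """

    n: int
    beta: float
    pi: float
    strategy: str = "uniform"
    nu: int = 1
    theta: float = 1.0
    pool: str = "cooperators"
    a: float = 1.0
    init: str = "all_D"
    burn_in: int = 500
    window: int = 500
    t_max: int = 2000
    realizations: int = 100
    seed: int = 0
    noise_sd: float = 0.0
    swap_fraction: float = 0.0
    het_scale: float = 1.0

    def rule(self) -> StrategyRule:
        return StrategyRule(kind=self.strategy, group_size=self.nu, threshold=self.theta)

    def params(self) -> DynamicsParams:
        return DynamicsParams(
            beta=self.beta, pi_cap=self.pi, pool=self.pool, punishing_fraction=self.a
        )

    def profile(self) -> PredispositionProfile:
        base = build_linear_profile(self.n)
        spec = PerturbationSpec(
            noise_sd=self.noise_sd,
            swap_fraction=self.swap_fraction,
            heterogeneity_scale=self.het_scale,
            seed=self.seed,
        )
        return spec.apply(base)

    def sim_config(self) -> SimulationConfig:
        init: object = self.init
        if isinstance(init, str) and init.startswith("density:"):
            init = float(init.split(":", 1)[1])
        return SimulationConfig(
            t_max=self.t_max,
            burn_in=self.burn_in,
            window=self.window,
            realizations=self.realizations,
            init=init,
            seed=self.seed,
        )


def _validate_run_config(raw: dict, source: str) -> RunConfig:
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{source}: unknown configuration key(s): {sorted(unknown)}")
    for key in ("n", "beta", "pi"):
        if key not in raw:
            raise ValueError(f"{source}: missing required key {key!r}")
    cfg = RunConfig(**raw)
    checks = {
        "n": cfg.n >= 3,
        "beta": cfg.beta >= 0,
        "pi": cfg.pi >= 0,
        "nu": 1 <= cfg.nu <= cfg.n,
        "theta": 0 < cfg.theta <= 1,
        "a": 0 < cfg.a <= 1,
        "burn_in": cfg.burn_in >= 0,
        "window": cfg.window > 0,
        "t_max": cfg.t_max >= cfg.burn_in + cfg.window,
        "realizations": cfg.realizations >= 1,
        "noise_sd": cfg.noise_sd >= 0,
        "swap_fraction": 0 <= cfg.swap_fraction <= 1,
        "het_scale": cfg.het_scale >= 0,
    }
    for key, ok in checks.items():
        if not ok:
            raise ValueError(f"{source}: value out of range for key {key!r}: {getattr(cfg, key)!r}")
    if cfg.strategy not in ("uniform", "single_file", "groups"):
        raise ValueError(f"{source}: value out of range for key 'strategy': {cfg.strategy!r}")
    if cfg.pool not in ("cooperators", "all", "fraction"):
        raise ValueError(f"{source}: value out of range for key 'pool': {cfg.pool!r}")
    if cfg.init not in _INITS and not cfg.init.startswith("density:"):
        raise ValueError(f"{source}: value out of range for key 'init': {cfg.init!r}")
    if cfg.init.startswith("density:"):
        dens = float(cfg.init.split(":", 1)[1])
        if not 0.0 <= dens <= 1.0:
            raise ValueError(f"{source}: initial density outside [0, 1]: {dens!r}")
    return cfg


def read_run_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration, filling defaults."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"{path}: malformed YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return _validate_run_config(raw, str(path))


def write_run_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=False))


# --------------------------------------------------------------------------
# grid I/O: long CSV + JSON sidecar


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_grid(grid: SweepGrid | SweepComparison, path: str | Path) -> None:
    """Write a grid as long-format CSV plus a ``<path>.meta.json`` sidecar."""
    path = Path(path)
    bb, pp = np.meshgrid(grid.beta_values, grid.pi_values, indexing="ij")
    if isinstance(grid, SweepComparison):
        frame = pd.DataFrame(
            {"beta": bb.ravel(), "pi": pp.ravel(), "value": grid.delta.ravel()}
        )
        meta = {"kind": "comparison", **grid.metadata}
    else:
        frame = pd.DataFrame(
            {
                "beta": bb.ravel(),
                "pi": pp.ravel(),
                "value": grid.value.ravel(),
                "se": grid.se.ravel(),
                "n_realizations": grid.metadata.get("realizations"),
                "censored_fraction": grid.censored_fraction.ravel(),
            }
        )
        meta = dict(grid.metadata)
    frame.to_csv(path, index=False, float_format="%.17g")
    _sidecar(path).write_text(json.dumps(meta, indent=2, default=str) + "\n")


def read_grid(path: str | Path) -> SweepGrid:
    """Read a grid written by :func:`write_grid` (sweep grids only)."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    if meta.get("kind") == "comparison":
        raise ValueError("comparison grids cannot be read back as SweepGrid")
    beta_values = np.unique(frame["beta"].to_numpy())
    pi_values = np.unique(frame["pi"].to_numpy())
    shape = (beta_values.size, pi_values.size)
    pivot = frame.sort_values(["beta", "pi"])
    value = pivot["value"].to_numpy().reshape(shape)
    se = pivot["se"].to_numpy().reshape(shape)
    censored = pivot["censored_fraction"].to_numpy().reshape(shape)
    return SweepGrid(
        beta_values=beta_values,
        pi_values=pi_values,
        value=value,
        se=se,
        censored_fraction=censored,
        kind=meta.get("kind", "rho"),
        metadata=meta,
    )
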