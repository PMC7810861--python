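"""Gillespie simulation of the network with tunable noise granularity.

Each node contributes two reaction channels: production of a quantum ``eta``
at propensity ``alpha * SA(X) / eta`` and decay of a quantum at propensity
``delta * [X] / eta``.  The expected drift therefore equals the deterministic
right-hand side for any ``eta``, while the variance scales linearly with
``eta`` (in the stationary birth–death case, [X] = eta * N with
N ~ Poisson(alpha/(delta*eta))).

The base granularity is 0.1.  PTB and RESTc operate near concentration 1
(the other factors nearer 5) and fit with markedly faster turnover, so their
granularity is reduced by 1/5 twice — an effective eta of 0.004 — to give
all five factors comparable relative noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .deterministic import Trajectory
from .engine import CompiledModel, _gillespie_kernel, compile_model
from .network import NetworkTopology, ParameterSet

DEFAULT_OUTPUT_GRID_H = 0.5
DEFAULT_ENSEMBLE_SIZE = 50
DEFAULT_SCENARIO_DURATION_H = 336.0  # 14 simulated days
MAX_EVENTS = 100_000_000


class NoiseConfigError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseConfig:
    """Granularity settings: effective eta per node = base * multiplier."""

    base: float = 0.1
    multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"PTB": 1.0 / 25.0, "RESTc": 1.0 / 25.0}
    )

    def __post_init__(self) -> None:
        if not self.base > 0:
            raise NoiseConfigError("base granularity must be strictly positive")
        for node, m in self.multipliers.items():
            if not m > 0:
                raise NoiseConfigError(f"multiplier for {node} must be positive")


def effective_eta(config: NoiseConfig, node: str, nodes: Sequence[str] | None = None) -> float:
    """Granularity used for ``node``'s production and decay channels."""
    if nodes is not None and node not in nodes:
        raise KeyError(f"unknown node {node!r}")
    return config.base * config.multipliers.get(node, 1.0)


def _eta_vector(config: NoiseConfig, nodes: Sequence[str]) -> np.ndarray:
    for name in config.multipliers:
        if name not in nodes:
            raise KeyError(f"noise multiplier refers to unknown node {name!r}")
    return np.array([effective_eta(config, n) for n in nodes])


def snap_to_eta(state: Mapping[str, float], config: NoiseConfig, nodes: Sequence[str]) -> dict[str, float]:
    """Round a state to non-negative integer multiples of each node's eta."""
    out = {}
    for n in nodes:
        eta = effective_eta(config, n)
        out[n] = max(0.0, round(state[n] / eta)) * eta
    return out


def gillespie_run(
    topology: NetworkTopology,
    params: ParameterSet,
    active_inputs: Iterable[str],
    initial_state: Mapping[str, float],
    duration_h: float,
    noise_config: NoiseConfig,
    seed: int,
    grid_h: float = DEFAULT_OUTPUT_GRID_H,
) -> Trajectory:
    """One stochastic trajectory, recorded on a uniform output grid.

    The initial state is snapped to multiples of each node's granularity.
    Identical seeds give identical trajectories (MT19937, seeded per run).
    """
    model = compile_model(topology, params, active_inputs)
    return _gillespie_on_model(model, initial_state, duration_h, noise_config, seed, grid_h)


def _gillespie_on_model(
    model: CompiledModel,
    initial_state: Mapping[str, float],
    duration_h: float,
    noise_config: NoiseConfig,
    seed: int,
    grid_h: float = DEFAULT_OUTPUT_GRID_H,
) -> Trajectory:
    nodes = model.nodes
    eta = _eta_vector(noise_config, nodes)
    snapped = snap_to_eta(dict(initial_state), noise_config, nodes)
    y0 = model.state_vector(snapped)
    n_grid = int(round(duration_h / grid_h)) + 1
    grid = np.arange(n_grid) * grid_h
    values = np.empty((n_grid, len(nodes)))
    events = _gillespie_kernel(
        y0,
        float(duration_h),
        eta,
        grid,
        model.alpha,
        model.delta,
        *model._term_args(),
        int(seed),
        MAX_EVENTS,
        values,
    )
    if events < 0:
        raise RuntimeError(
            f"stochastic run exceeded the event budget ({MAX_EVENTS}) "
            f"before t = {duration_h} h"
        )
    return Trajectory(
        grid,
        values,
        nodes,
        stage="stochastic",
        meta={"seed": int(seed), "events": int(events)},
    )


def run_ensemble(
    topology: NetworkTopology,
    params: ParameterSet,
    active_inputs: Iterable[str],
    initial_state: Mapping[str, float],
    noise_config: NoiseConfig,
    seeds: Sequence[int] | None = None,
    n_runs: int = DEFAULT_ENSEMBLE_SIZE,
    duration_h: float = DEFAULT_SCENARIO_DURATION_H,
    grid_h: float = DEFAULT_OUTPUT_GRID_H,
    base_seed: int = 0,
) -> list[Trajectory]:
    """Independent stochastic replicates of a 14-day (default) scenario.

    ``seeds`` must be distinct when given; otherwise seeds are derived as
    base_seed, base_seed + 1, ...
    """
    if seeds is None:
        seeds = [int(base_seed) + i for i in range(n_runs)]
    seeds = [int(s) for s in seeds]
    if len(set(seeds)) != len(seeds):
        raise ValueError("ensemble seeds must be distinct")
    if len(seeds) < 1:
        raise ValueError("at least one run is required")
    model = compile_model(topology, params, active_inputs)
    runs = []
    for i, s in enumerate(seeds):
        traj = _gillespie_on_model(model, initial_state, duration_h, noise_config, s, grid_h)
        traj.meta["run"] = i
        runs.append(traj)
    return runs


def ensemble_to_frame(runs: Sequence[Trajectory]):
    """Tidy frame with run index and seed columns."""
    import pandas as pd

    frames = []
    for traj in runs:
        f = traj.to_frame()
        f["run"] = traj.meta.get("run", -1)
        f["seed"] = traj.meta.get("seed", -1)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)
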