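"""In-silico overexpression/knockdown scenarios and conversion calls.

Perturbations act on the fitted parameters: overexpression multiplies a
node's transcription coefficient alpha by 5 and knockdown by 1/5, while
Ascl1 overexpression and REST knockdown — the two experimentally wired
inputs — are realised by toggling the viral-Ascl1 activator and the shREST
inhibitor on or off, exactly as during training.  Each scenario is run as a
single 14-day window from the fibroblast baseline, deterministically and as
a stochastic ensemble (50 runs by default).

A stochastic run counts as a neuronal conversion when endogenous Ascl1
reaches 1 (the detection-limit unit) at any time; a scenario converts when
at least one of the runs does.  For Ascl1 OX + REST KD — a conversion
built into the training data — the grid additionally reports whether its
efficiency strictly exceeds Ascl1 OX alone (the "Yes+" flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .deterministic import integrate_stage
from .engine import compile_model
from .network import (
    NetworkTopology,
    ParameterSet,
    RESTI,
    VASCL1,
    fibroblast_baseline,
)
from .stochastic import (
    DEFAULT_SCENARIO_DURATION_H,
    NoiseConfig,
    run_ensemble,
)

OX_FACTOR = 5.0
KD_FACTOR = 1.0 / 5.0
DEEP_KD_FACTOR = 1.0 / 5000.0
CONVERSION_THRESHOLD = 1.0


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioSpec:
    """One perturbation: alpha multipliers, input toggles, beta multipliers."""

    name: str
    alpha_mult: Mapping[str, float] = field(default_factory=dict)
    resti_on: bool = False
    vascl1_on: bool = False
    beta_mult: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for table in (self.alpha_mult, self.beta_mult):
            for node, m in table.items():
                if not m > 0:
                    raise ScenarioError(f"multiplier for {node} must be positive")

    @property
    def active_inputs(self) -> frozenset[str]:
        active = set()
        if self.resti_on:
            active.add(RESTI)
        if self.vascl1_on:
            active.add(VASCL1)
        return frozenset(active)


def canonical_grid() -> tuple[ScenarioSpec, ...]:
    """The eight-scenario experiment grid."""
    return (
        ScenarioSpec("Fibroblast"),
        ScenarioSpec("OX Ascl1", vascl1_on=True),
        ScenarioSpec("OX miRs", alpha_mult={"miRs": OX_FACTOR}),
        ScenarioSpec("KD REST", resti_on=True),
        ScenarioSpec("OX Ascl1 + KD REST", vascl1_on=True, resti_on=True),
        ScenarioSpec("OX Ascl1 + OX REST", vascl1_on=True, alpha_mult={"RESTc": OX_FACTOR}),
        ScenarioSpec("OX Ascl1 + OX PTB", vascl1_on=True, alpha_mult={"PTB": OX_FACTOR}),
        ScenarioSpec("KD PTB", alpha_mult={"PTB": KD_FACTOR}),
    )


def apply_scenario(params: ParameterSet, spec: ScenarioSpec) -> ParameterSet:
    """Perturbed copy of ``params``; double application raises.

    Ascl1 overexpression must go through the viral input, never through
    alpha_Ascl1 — requesting both mechanisms at once is ambiguous.
    """
    if params.scenario is not None:
        raise ScenarioError(
            f"parameters already carry scenario {params.scenario!r}; "
            "multipliers must not compose silently"
        )
    if "Ascl1" in spec.alpha_mult and spec.vascl1_on:
        raise ScenarioError(
            "choose one Ascl1 overexpression mechanism: viral input or alpha"
        )
    for node in list(spec.alpha_mult) + list(spec.beta_mult):
        if node not in params.alpha and node not in params.beta:
            raise ScenarioError(f"scenario refers to unknown node {node!r}")
    alpha = {n: v * spec.alpha_mult.get(n, 1.0) for n, v in params.alpha.items()}
    beta = {n: v * spec.beta_mult.get(n, 1.0) for n, v in params.beta.items()}
    return params.replace(alpha=alpha, beta=beta, scenario=spec.name)


@dataclass
class ConversionCall:
    converted: bool
    efficiency: float
    n_converted: int
    n_runs: int


def classify_conversion(
    ensemble: Sequence,
    threshold: float = CONVERSION_THRESHOLD,
    min_hits: int = 1,
    strict: bool = False,
    node: str = "Ascl1",
) -> ConversionCall:
    """Call conversion from the endogenous-Ascl1 maxima of an ensemble.

    A run converts when its Ascl1 maximum reaches ``threshold`` (>= by
    default; ``strict`` switches to >).  The scenario converts when at
    least ``min_hits`` runs do; efficiency is the converting fraction.
    """
    if len(ensemble) == 0:
        raise ScenarioError("ensemble must be non-empty")
    hits = 0
    for traj in ensemble:
        peak = float(np.max(traj.series(node)))
        crossed = peak > threshold if strict else peak >= threshold
        if crossed:
            hits += 1
    return ConversionCall(
        converted=hits >= min_hits,
        efficiency=hits / len(ensemble),
        n_converted=hits,
        n_runs=len(ensemble),
    )


def run_scenario(
    topology: NetworkTopology,
    params: ParameterSet,
    spec: ScenarioSpec,
    noise_config: NoiseConfig,
    base_seed: int,
    n_runs: int = 50,
    duration_h: float = DEFAULT_SCENARIO_DURATION_H,
) -> dict:
    """Deterministic trajectory + stochastic ensemble + conversion call."""
    perturbed = apply_scenario(params, spec)
    initial = fibroblast_baseline(topology)
    model = compile_model(topology, perturbed, spec.active_inputs)
    det = integrate_stage(model, initial, duration_h, stage=spec.name)
    ensemble = run_ensemble(
        topology,
        perturbed,
        spec.active_inputs,
        initial,
        noise_config,
        n_runs=n_runs,
        duration_h=duration_h,
        base_seed=base_seed,
    )
    call = classify_conversion(ensemble)
    return {
        "spec": spec,
        "deterministic": det,
        "ensemble": ensemble,
        "call": call,
        "deterministic_peak_ascl1": float(np.max(det.series("Ascl1"))),
    }


def scenario_table(
    topology: NetworkTopology,
    params: ParameterSet,
    grid: Sequence[ScenarioSpec] | None = None,
    noise_config: NoiseConfig | None = None,
    base_seed: int = 0,
    n_runs: int = 50,
    duration_h: float = DEFAULT_SCENARIO_DURATION_H,
) -> pd.DataFrame:
    """Outcome table over a scenario grid.

    Columns: scenario, deterministic_peak_ascl1, n_converted, n_runs,
    efficiency, call, plus_flag.  plus_flag is set only on the
    "OX Ascl1 + KD REST" row and records strict efficiency dominance over
    "OX Ascl1" alone.
    """
    grid = tuple(grid or canonical_grid())
    noise_config = noise_config or NoiseConfig()
    rows = []
    results = {}
    for i, spec in enumerate(grid):
        res = run_scenario(
            topology, params, spec, noise_config,
            base_seed=base_seed + 1000 * i, n_runs=n_runs, duration_h=duration_h,
        )
        results[spec.name] = res
        rows.append(
            {
                "scenario": spec.name,
                "deterministic_peak_ascl1": res["deterministic_peak_ascl1"],
                "n_converted": res["call"].n_converted,
                "n_runs": res["call"].n_runs,
                "efficiency": res["call"].efficiency,
                "call": "Yes" if res["call"].converted else "No",
                "plus_flag": False,
            }
        )
    table = pd.DataFrame(rows)
    if "OX Ascl1 + KD REST" in results and "OX Ascl1" in results:
        dom = (
            results["OX Ascl1 + KD REST"]["call"].efficiency
            > results["OX Ascl1"]["call"].efficiency
        )
        table.loc[table["scenario"] == "OX Ascl1 + KD REST", "plus_flag"] = dom
    return table


def deep_ptb_kd_probe(
    topology: NetworkTopology,
    params: ParameterSet,
    noise_config: NoiseConfig | None = None,
    base_seed: int = 0,
    n_runs: int = 50,
    alpha_mult: float = DEEP_KD_FACTOR,
    beta_r_mult: float = KD_FACTOR,
    duration_h: float = DEFAULT_SCENARIO_DURATION_H,
) -> dict[str, ConversionCall]:
    """Deep PTB knockdown with and without reduced constitutive REST drive.

    Knocking PTB's transcription down even 5000-fold leaves the background
    activation of RESTc holding the network in the fibroblast state; the
    probe reruns the same knockdown with beta_RESTc reduced (1/5) to show
    that this background is what blocks conversion.
    """
    if "RESTc" not in params.beta:
        raise ScenarioError(
            "deep PTB-KD probe requires a constitutive RESTc background (beta)"
        )
    noise_config = noise_config or NoiseConfig()
    out = {}
    for label, beta_m in (("kd_only", 1.0), ("kd_with_reduced_rest_background", beta_r_mult)):
        spec = ScenarioSpec(
            f"deep KD PTB ({label})",
            alpha_mult={"PTB": alpha_mult},
            beta_mult={"RESTc": beta_m} if beta_m != 1.0 else {},
        )
        res = run_scenario(
            topology, params, spec, noise_config,
            base_seed=base_seed, n_runs=n_runs, duration_h=duration_h,
        )
        out[label] = res["call"]
    return out
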