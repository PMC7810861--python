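"""YAML/CSV interchange for topologies, protocols, and parameter sets."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .network import (
    NetworkTopology,
    ParameterSet,
    Stage,
    StageProtocol,
    STAGE_INPUTS,
)


def topology_to_dict(topology: NetworkTopology) -> dict:
    return {
        "nodes": list(topology.nodes),
        "edges": [list(e) for e in topology.regulatory_edges()],
        "external_inputs": [list(e) for e in sorted(topology.external_inputs)],
        "permitted_self": [list(p) for p in sorted(topology.permitted_self)],
    }


def topology_from_dict(d: Mapping) -> NetworkTopology:
    return NetworkTopology(
        nodes=tuple(d["nodes"]),
        edges=frozenset(tuple(e) for e in d["edges"]),
        external_inputs=frozenset(tuple(e) for e in d.get("external_inputs", [])),
        permitted_self=frozenset(tuple(p) for p in d.get("permitted_self", [])),
    )


def protocol_to_dict(protocol: StageProtocol) -> dict:
    return {
        "stages": [
            {
                "name": s.name,
                "duration_h": float(s.duration_h),
                "active_inputs": sorted(s.active_inputs),
            }
            for s in protocol
        ]
    }


def protocol_from_dict(d: Mapping) -> StageProtocol:
    stages = []
    for s in d["stages"]:
        active = s.get("active_inputs")
        if active is None:
            active = sorted(STAGE_INPUTS.get(s["name"], frozenset()))
        stages.append(Stage(s["name"], float(s["duration_h"]), frozenset(active)))
    return StageProtocol(tuple(stages))


def save_topology(topology: NetworkTopology, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(topology_to_dict(topology), sort_keys=False))


def load_topology(path: str | Path) -> NetworkTopology:
    return topology_from_dict(yaml.safe_load(Path(path).read_text()))


def params_to_csv(params: ParameterSet, path: str | Path) -> None:
    """Flat two-column table (parameter, value), Supplementary-table style."""
    flat = params.as_flat()
    pd.DataFrame({"parameter": list(flat), "value": list(flat.values())}).to_csv(
        path, index=False
    )


def params_from_csv(path: str | Path, topology: NetworkTopology) -> ParameterSet:
    frame = pd.read_csv(path)
    flat = dict(zip(frame["parameter"], frame["value"]))
    alpha = {n: float(flat[f"alpha_{n}"]) for n in topology.nodes}
    delta = {n: float(flat[f"delta_{n}"]) for n in topology.nodes}
    beta = {n: float(flat[f"beta_{n}"]) for n in topology.beta_nodes}
    k = {(s, t): float(flat[f"k_{s}_{t}"]) for s, t, _ in topology.edges}
    h = {(s, t): float(flat[f"h_{s}_{t}"]) for s, t, _ in topology.edges}
    params = ParameterSet(
        alpha, delta, beta, k, h, float(flat["beta_RESTi"]), float(flat["beta_vAscl1"])
    )
    params.validate(topology)
    return params
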