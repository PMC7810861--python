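"""Arrow dissection: per-regulator influence on each node's transcription rate.

At any state, a node's transcription activity SA = S_act / (1 + S_act + S_inh)
(with S_act including the constitutive background and any active external
activator) is decomposed into

    L_act = S_act / (1 + S_act)                        (upward arrows)
    L_inh = S_act * S_inh / ((1 + S_act)(1 + S_act + S_inh))   (downward)

so that L_act - L_inh = SA identically: L_act is the activity that would be
realised with no inhibitors present, and the inhibition arrows account for
the shortfall.  Individual regulators get sub-lengths proportional to their
(T/k)^h term.  A decay arrow of length (delta/alpha)*[X] is added so that the
net arrow sum equals the rate of change in units of alpha.

Nodes in the pure-repression form (no activators, no background) have an
unopposed maximal drive: L_act = 1, carried by a single "constitutive"
pseudo-regulator, and L_inh = S_inh / (1 + S_inh) = 1 - SA.  External inputs
appear as the pseudo-regulators "shREST" and "viral_Ascl1", the background as
"constitutive".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .deterministic import Trajectory
from .network import (
    NetworkTopology,
    ParameterSet,
    STAGE_INPUTS,
    StageProtocol,
)

CONSTITUTIVE = "constitutive"
PSEUDO_RESTI = "shREST"
PSEUDO_VASCL1 = "viral_Ascl1"


@dataclass
class ArrowSet:
    """Arrow lengths for one node at one state."""

    node: str
    l_act: float
    l_inh: float
    act_split: dict[str, float]
    inh_split: dict[str, float]
    decay: float
    activity: float

    def net_rate_over_alpha(self) -> float:
        """(d[X]/dt) / alpha_X: upward minus downward arrows."""
        return self.l_act - self.l_inh - self.decay


def arrow_lengths(
    node: str,
    state: Mapping[str, float],
    topology: NetworkTopology,
    params: ParameterSet,
    active_inputs: Iterable[str] = (),
) -> ArrowSet:
    topology._check_node(node)
    if params.alpha[node] <= 0:
        raise ValueError(f"alpha for {node} must be positive to scale arrows")
    active = frozenset(active_inputs)

    act_terms: dict[str, float] = {}
    for src in topology.activators_of(node):
        act_terms[src] = (state[src] / params.k[(src, node)]) ** params.h[(src, node)]
    if topology.has_beta(node):
        act_terms[CONSTITUTIVE] = params.beta[node]
    if topology.external_activator_of(node) in active:
        act_terms[PSEUDO_VASCL1] = params.beta_vascl1

    inh_terms: dict[str, float] = {}
    for src in topology.inhibitors_of(node):
        inh_terms[src] = (state[src] / params.k[(src, node)]) ** params.h[(src, node)]
    if topology.external_inhibitor_of(node) in active:
        inh_terms[PSEUDO_RESTI] = params.beta_resti

    s_inh = sum(inh_terms.values())
    if act_terms:
        s_act = sum(act_terms.values())
        l_act = s_act / (1.0 + s_act)
        l_inh = s_act * s_inh / ((1.0 + s_act) * (1.0 + s_act + s_inh))
        sa = s_act / (1.0 + s_act + s_inh)
        act_split = (
            {r: l_act * v / s_act for r, v in act_terms.items()} if s_act > 0 else {}
        )
    else:
        # pure-repression form: maximal drive is the constitutive unit rate
        l_act = 1.0
        l_inh = s_inh / (1.0 + s_inh)
        sa = 1.0 / (1.0 + s_inh)
        act_split = {CONSTITUTIVE: 1.0}
    inh_split = (
        {r: l_inh * v / s_inh for r, v in inh_terms.items()} if s_inh > 0 else {}
    )
    decay = params.delta[node] / params.alpha[node] * state[node]
    return ArrowSet(node, l_act, l_inh, act_split, inh_split, decay, sa)


def dissect_state(
    state: Mapping[str, float],
    topology: NetworkTopology,
    params: ParameterSet,
    active_inputs: Iterable[str] = (),
) -> dict[str, ArrowSet]:
    return {
        n: arrow_lengths(n, state, topology, params, active_inputs)
        for n in topology.nodes
    }


def dissect_trajectory(
    trajectory: Trajectory,
    topology: NetworkTopology,
    params: ParameterSet,
    protocol: StageProtocol | None = None,
    stride: int = 1,
) -> pd.DataFrame:
    """Arrow profile along a trajectory, long format.

    Columns: time_h, node, regulator, class (act / inh / decay), length,
    plus the realised activity per (time, node).  Active inputs follow the
    trajectory's stage annotation (looked up in the protocol when given,
    otherwise in the canonical stage table).
    """
    stage = trajectory.stage or "fibroblast"
    if protocol is not None:
        active = protocol.stage(stage).active_inputs
    elif stage in STAGE_INPUTS:
        active = STAGE_INPUTS[stage]
    else:
        active = frozenset()
    rows = []
    for i in range(0, len(trajectory.times), stride):
        state = {n: trajectory.values[i, j] for j, n in enumerate(trajectory.nodes)}
        t = float(trajectory.times[i])
        for node in topology.nodes:
            arrows = arrow_lengths(node, state, topology, params, active)
            for reg, length in arrows.act_split.items():
                rows.append((t, node, reg, "act", length, arrows.activity))
            for reg, length in arrows.inh_split.items():
                rows.append((t, node, reg, "inh", length, arrows.activity))
            rows.append((t, node, "decay", "decay", arrows.decay, arrows.activity))
    return pd.DataFrame(
        rows, columns=["time_h", "node", "regulator", "class", "length", "activity"]
    )


def reconstruction_error(
    trajectory: Trajectory,
    topology: NetworkTopology,
    params: ParameterSet,
    active_inputs: Iterable[str] = (),
) -> float:
    """Max |alpha*(L_act - L_inh) - delta*[X] - numerical df/dt| over the grid.

    The net arrow sum must reproduce the trajectory's rate of change up to
    finite-difference error on the integration grid.
    """
    worst = 0.0
    times = trajectory.times
    for j, node in enumerate(trajectory.nodes):
        f = trajectory.values[:, j]
        dfdt = np.gradient(f, times)
        for i in range(1, len(times) - 1):
            state = {n: trajectory.values[i, m] for m, n in enumerate(trajectory.nodes)}
            arrows = arrow_lengths(node, state, topology, params, active_inputs)
            model_rate = params.alpha[node] * (arrows.l_act - arrows.l_inh) - (
                params.delta[node] * state[node]
            )
            worst = max(worst, abs(model_rate - dfdt[i]))
    return worst
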