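"""Signed regulatory-network topologies and Shea–Ackers rate laws.

The core model describes five RNA species driving direct fibroblast-to-neuron
conversion: the splicing repressor PTB, its neural paralog nPTB, the neuronal
microRNA pool miRs (miR-124 + miR-9/9*), the REST repressor complex RESTc
(REST + SCP1), and endogenous Ascl1.  Transcriptional activity of each node is
the Shea–Ackers occupancy ratio

    SA(X) = (beta_X + sum_act (T/k)^h + ext_act)
            / (1 + beta_X + sum_act (T/k)^h + ext_act + sum_inh (T/k)^h + ext_inh)

where the sums run over the node's explicit activators/inhibitors, ``beta_X``
folds all constitutive (out-of-network) activation into one background
constant, and ``ext_*`` are the two experimental inputs: shREST knockdown
(``beta_RESTi``, a constant inhibitor of RESTc) and viral Ascl1
(``beta_vAscl1``, a constant activator of miRs).  A node with no activators
and no background reduces to the pure-repression form 1/(1 + sum_inh).

Concentrations are relative to the fibroblast baseline (= 1); time is in
hours.  Each node evolves as d[X]/dt = alpha_X * SA(X) - delta_X * [X].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

ACTIVATION = "activation"
INHIBITION = "inhibition"
SIGNS = (ACTIVATION, INHIBITION)

#: Canonical node set, in fixed order (PTB, nPTB, miRs, RESTc, Ascl1).
CANONICAL_NODES = ("PTB", "nPTB", "miRs", "RESTc", "Ascl1")

#: External experimental inputs: shREST inhibits RESTc, viral Ascl1 activates miRs.
RESTI = "RESTi"
VASCL1 = "vAscl1"

Edge = tuple[str, str, str]  # (source, target, sign)


class TopologyError(ValueError):
    """Raised for malformed topologies or edge-constraint violations."""


class ParameterError(ValueError):
    """Raised when a parameter set does not match its topology or is invalid."""


class DomainError(ValueError):
    """Raised for out-of-domain state values (e.g. negative concentrations)."""


@dataclass(frozen=True)
class NetworkTopology:
    """A signed directed regulatory graph plus external-input attachments.

    ``permitted_self`` lists (source, target) pairs for which a self-edge is
    tolerated; only variant families that model experimentally observed
    self-inhibition set it.
    """

    nodes: tuple[str, ...]
    edges: frozenset[Edge]
    external_inputs: frozenset[Edge] = frozenset()
    permitted_self: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise TopologyError("duplicate node identifiers")
        seen_pairs: set[tuple[str, str]] = set()
        for src, tgt, sign in self.edges:
            if sign not in SIGNS:
                raise TopologyError(f"unknown edge sign {sign!r}")
            if src not in node_set or tgt not in node_set:
                raise TopologyError(f"edge ({src}, {tgt}) references undeclared node")
            if src == tgt and (src, tgt) not in self.permitted_self:
                raise TopologyError(f"self-edge on {src} is not allowed")
            if (src, tgt) in seen_pairs:
                raise TopologyError(
                    f"double interaction between {src} and {tgt} is not allowed"
                )
            seen_pairs.add((src, tgt))
        for name, tgt, sign in self.external_inputs:
            if tgt not in node_set:
                raise TopologyError(f"external input {name} targets unknown node {tgt}")
            if sign not in SIGNS:
                raise TopologyError(f"unknown external-input sign {sign!r}")

    # -- structure queries ------------------------------------------------

    def activators_of(self, node: str) -> tuple[str, ...]:
        self._check_node(node)
        return tuple(
            sorted(s for s, t, g in self.edges if t == node and g == ACTIVATION)
        )

    def inhibitors_of(self, node: str) -> tuple[str, ...]:
        self._check_node(node)
        return tuple(
            sorted(s for s, t, g in self.edges if t == node and g == INHIBITION)
        )

    def external_activator_of(self, node: str) -> str | None:
        for name, tgt, sign in self.external_inputs:
            if tgt == node and sign == ACTIVATION:
                return name
        return None

    def external_inhibitor_of(self, node: str) -> str | None:
        for name, tgt, sign in self.external_inputs:
            if tgt == node and sign == INHIBITION:
                return name
        return None

    def has_beta(self, node: str) -> bool:
        """Whether the node carries a constitutive background term beta_X.

        A node acquires a background exactly when it has at least one
        activator — a regulatory edge or an attached external activating
        input.  Nodes with neither reduce to the 1/(1 + sum_inh) form in
        which a background constant would be redundant.
        """
        return bool(self.activators_of(node)) or (
            self.external_activator_of(node) is not None
        )

    @property
    def beta_nodes(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if self.has_beta(n))

    def regulatory_edges(self) -> tuple[Edge, ...]:
        return tuple(sorted(self.edges))

    def _check_node(self, node: str) -> None:
        if node not in self.nodes:
            raise TopologyError(f"unknown node {node!r}")

    # -- variants ---------------------------------------------------------

    def with_edge(self, source: str, target: str, sign: str) -> "NetworkTopology":
        """Return a copy with one added interaction (no self/double edges)."""
        self._check_node(source)
        self._check_node(target)
        if sign not in SIGNS:
            raise TopologyError(f"unknown edge sign {sign!r}")
        if source == target and (source, target) not in self.permitted_self:
            raise TopologyError(f"self-edge {source}->{target} is not allowed")
        for s, t, _ in self.edges:
            if (s, t) == (source, target):
                raise TopologyError(
                    f"pair ({source}, {target}) already carries an edge; "
                    "double interactions are not allowed"
                )
        return replace(self, edges=self.edges | {(source, target, sign)})


def add_edge_variant(
    topology: NetworkTopology, source: str, target: str, sign: str
) -> NetworkTopology:
    """Functional alias for :meth:`NetworkTopology.with_edge`."""
    return topology.with_edge(source, target, sign)


def literature_topology() -> NetworkTopology:
    """The literature-curated network: 7 signed edges among the 5 nodes."""
    edges = frozenset(
        {
            ("miRs", "PTB", INHIBITION),
            ("miRs", "nPTB", INHIBITION),
            ("PTB", "nPTB", INHIBITION),
            ("miRs", "RESTc", INHIBITION),
            ("PTB", "RESTc", ACTIVATION),
            ("RESTc", "miRs", INHIBITION),
            ("RESTc", "Ascl1", INHIBITION),
        }
    )
    externals = frozenset(
        {
            (RESTI, "RESTc", INHIBITION),
            (VASCL1, "miRs", ACTIVATION),
        }
    )
    return NetworkTopology(CANONICAL_NODES, edges, externals)


def nptb_to_ptb_topology() -> NetworkTopology:
    """Literature network plus the nPTB -> PTB activation (the best model)."""
    return literature_topology().with_edge("nPTB", "PTB", ACTIVATION)


# ---------------------------------------------------------------------------
# Parameters


@dataclass(frozen=True)
class ParameterSet:
    """All rate and interaction constants for one topology.

    alpha: transcription coefficients (concentration/h); delta: decay (1/h);
    beta: constitutive background per beta-carrying node (dimensionless);
    k, h: per-edge dissociation constants and Hill exponents (h in (0, 4]);
    beta_resti / beta_vascl1: external input strengths (dimensionless).
    ``scenario`` tags a set that has been perturbed, so perturbations never
    compose silently.
    """

    alpha: Mapping[str, float]
    delta: Mapping[str, float]
    beta: Mapping[str, float]
    k: Mapping[tuple[str, str], float]
    h: Mapping[tuple[str, str], float]
    beta_resti: float
    beta_vascl1: float
    scenario: str | None = None

    HILL_MAX = 4.0

    def validate(self, topology: NetworkTopology) -> None:
        nodes = set(topology.nodes)
        for name, table in (("alpha", self.alpha), ("delta", self.delta)):
            if set(table) != nodes:
                raise ParameterError(f"{name} keys must match topology nodes")
            for n, v in table.items():
                if not v > 0:
                    raise ParameterError(f"{name}[{n}] must be strictly positive")
        beta_nodes = set(topology.beta_nodes)
        if set(self.beta) != beta_nodes:
            raise ParameterError(
                f"beta keys {sorted(self.beta)} must match background-carrying "
                f"nodes {sorted(beta_nodes)}"
            )
        for n, v in self.beta.items():
            if not v > 0:
                raise ParameterError(f"beta[{n}] must be strictly positive")
        pairs = {(s, t) for s, t, _ in topology.edges}
        for name, table in (("k", self.k), ("h", self.h)):
            if set(table) != pairs:
                raise ParameterError(f"{name} keys must match topology edges")
            for pair, v in table.items():
                if not v > 0:
                    raise ParameterError(f"{name}[{pair}] must be strictly positive")
        for pair, v in self.h.items():
            if v > self.HILL_MAX:
                raise ParameterError(f"h[{pair}] exceeds the cap of {self.HILL_MAX}")
        if not (self.beta_resti > 0 and self.beta_vascl1 > 0):
            raise ParameterError("external input strengths must be strictly positive")

    def as_flat(self) -> dict[str, float]:
        """Flat {parameter name: value} view (Supplementary-table layout)."""
        out: dict[str, float] = {}
        for n in sorted(self.alpha):
            out[f"alpha_{n}"] = float(self.alpha[n])
        for n in sorted(self.delta):
            out[f"delta_{n}"] = float(self.delta[n])
        for n in sorted(self.beta):
            out[f"beta_{n}"] = float(self.beta[n])
        for (s, t) in sorted(self.k):
            out[f"k_{s}_{t}"] = float(self.k[(s, t)])
        for (s, t) in sorted(self.h):
            out[f"h_{s}_{t}"] = float(self.h[(s, t)])
        out["beta_RESTi"] = float(self.beta_resti)
        out["beta_vAscl1"] = float(self.beta_vascl1)
        return out

    def replace(self, **changes) -> "ParameterSet":
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# Stage protocol


@dataclass(frozen=True)
class Stage:
    name: str
    duration_h: float
    active_inputs: frozenset[str] = frozenset()


STAGE_INPUTS: dict[str, frozenset[str]] = {
    "fibroblast": frozenset(),
    "rest_kd": frozenset({RESTI}),
    "conversion": frozenset({RESTI, VASCL1}),
}


@dataclass(frozen=True)
class StageProtocol:
    stages: tuple[Stage, ...]

    def __iter__(self):
        return iter(self.stages)

    def stage(self, name: str) -> Stage:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(f"no stage named {name!r}")


def canonical_protocol(
    fibroblast_h: float = 72.0,
    rest_kd_h: float = 72.0,
    conversion_h: float = 504.0,
) -> StageProtocol:
    """fibroblast (inputs off) -> 3 d REST knockdown -> 21 d conversion."""
    return StageProtocol(
        (
            Stage("fibroblast", fibroblast_h, STAGE_INPUTS["fibroblast"]),
            Stage("rest_kd", rest_kd_h, STAGE_INPUTS["rest_kd"]),
            Stage("conversion", conversion_h, STAGE_INPUTS["conversion"]),
        )
    )


def stage_effective_params(params: ParameterSet, stage: Stage | str) -> ParameterSet:
    """Zero the external-input strengths that are inactive in ``stage``.

    fibroblast: both off; rest_kd: only shREST acts; conversion: both act.
    Returned sets are only meant for inspection/export — the simulators pass
    ``active_inputs`` explicitly so strictly-positive invariants stay intact.
    """
    name = stage if isinstance(stage, str) else stage.name
    if name not in STAGE_INPUTS:
        raise KeyError(f"unknown stage {name!r}")
    active = STAGE_INPUTS[name]
    return replace(
        params,
        beta_resti=params.beta_resti if RESTI in active else 0.0,
        beta_vascl1=params.beta_vascl1 if VASCL1 in active else 0.0,
    )


# ---------------------------------------------------------------------------
# Shea–Ackers activity and ODE right-hand side (reference implementation)


def shea_ackers_activity(
    node: str,
    state: Mapping[str, float],
    topology: NetworkTopology,
    params: ParameterSet,
    active_inputs: Iterable[str] = (),
) -> float:
    """Occupancy-based transcription activity of ``node``, in [0, 1].

    This is the readable dictionary-based form; the simulators use a
    compiled array version (see :mod:`neurogrn.engine`) that is tested to
    agree with this one.
    """
    topology._check_node(node)
    active = frozenset(active_inputs)
    for n in topology.nodes:
        if state[n] < 0:
            raise DomainError(f"negative concentration for {n}")

    s_act = 0.0
    for src in topology.activators_of(node):
        s_act += (state[src] / params.k[(src, node)]) ** params.h[(src, node)]
    s_inh = 0.0
    for src in topology.inhibitors_of(node):
        s_inh += (state[src] / params.k[(src, node)]) ** params.h[(src, node)]

    ext_act = 0.0
    if topology.external_activator_of(node) in active:
        ext_act = params.beta_vascl1
    ext_inh = 0.0
    if topology.external_inhibitor_of(node) in active:
        ext_inh = params.beta_resti

    if topology.has_beta(node):
        num = params.beta[node] + s_act + ext_act
        return num / (1.0 + num + s_inh + ext_inh)
    # Pure-repression (reduced) form: background folded away.
    return 1.0 / (1.0 + s_inh + ext_inh)


def ode_rhs(
    topology: NetworkTopology,
    params: ParameterSet,
    active_inputs: Iterable[str] = (),
):
    """Return f(state) -> {node: d[X]/dt} with the given inputs active."""
    active = frozenset(active_inputs)

    def rhs(state: Mapping[str, float]) -> dict[str, float]:
        return {
            n: params.alpha[n]
            * shea_ackers_activity(n, state, topology, params, active)
            - params.delta[n] * state[n]
            for n in topology.nodes
        }

    return rhs


def fibroblast_baseline(topology: NetworkTopology) -> dict[str, float]:
    """Measured fibroblast state: all factors at 1, endogenous Ascl1 absent."""
    return {n: (0.0 if n == "Ascl1" else 1.0) for n in topology.nodes}


def decay_halflife(delta: float) -> float:
    """Half-life in hours for an exponential decay coefficient (1/h)."""
    return math.log(2.0) / delta
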