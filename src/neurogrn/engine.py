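"""Array-compiled model representation and numba kernels.

The dictionary-based rate laws in :mod:`neurogrn.network` are readable but far
too slow for parameter fitting (tens of thousands of protocol integrations)
or for stochastic ensembles (millions of reaction events).  This module
flattens a (topology, parameters, active inputs) triple into contiguous
arrays — a CSR-like layout of activator/inhibitor terms per node — and
provides jit-compiled kernels for:

* the Shea–Ackers activity vector,
* the ODE right-hand side,
* fixed-step RK4 integration (step 0.05 h, final partial step, endpoints
  inclusive, negative values clamped to 0 with a counter),
* the Gillespie direct method with per-node granularity eta (production
  steps +eta at rate alpha*SA/eta, decay steps -eta at rate delta*[X]/eta).

The kernels are deterministic given their seed; the stochastic kernel uses
numba's np.random (MT19937 semantics), seeded per run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from numba import njit

from .network import NetworkTopology, ParameterSet, RESTI, VASCL1


class IntegrationError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""

    def __init__(self, time_h: float, stage: str = ""):
        where = f" in stage {stage!r}" if stage else ""
        super().__init__(f"non-finite state at t = {time_h:.3f} h{where}")
        self.time_h = time_h
        self.stage = stage


@dataclass
class CompiledModel:
    """Flat-array view of one model under a fixed set of active inputs."""

    nodes: tuple[str, ...]
    alpha: np.ndarray
    delta: np.ndarray
    act_ptr: np.ndarray  # int64, len n+1
    act_src: np.ndarray  # int64 regulator indices
    act_k: np.ndarray
    act_h: np.ndarray
    inh_ptr: np.ndarray
    inh_src: np.ndarray
    inh_k: np.ndarray
    inh_h: np.ndarray
    beta: np.ndarray  # background; 0 where absent
    pure_repression: np.ndarray  # bool: node has the 1/(1+sum_inh) form
    num_add: np.ndarray  # active external activator strength per node
    den_add: np.ndarray  # active external inhibitor strength per node

    def index(self, node: str) -> int:
        return self.nodes.index(node)

    def state_vector(self, state: Mapping[str, float]) -> np.ndarray:
        return np.array([state[n] for n in self.nodes], dtype=np.float64)

    def state_dict(self, vec: np.ndarray) -> dict[str, float]:
        return {n: float(vec[i]) for i, n in enumerate(self.nodes)}

    def activities(self, state: np.ndarray) -> np.ndarray:
        out = np.empty(len(self.nodes))
        _sa_kernel(np.asarray(state, dtype=np.float64), *self._term_args(), out)
        return out

    def rhs(self, state: np.ndarray) -> np.ndarray:
        out = np.empty(len(self.nodes))
        _rhs_kernel(
            np.asarray(state, dtype=np.float64),
            self.alpha,
            self.delta,
            *self._term_args(),
            out,
        )
        return out

    def rhs_batch(self, states: np.ndarray) -> np.ndarray:
        """Right-hand side evaluated row-wise for a (m, n_nodes) state array."""
        states = np.ascontiguousarray(states, dtype=np.float64)
        out = np.empty_like(states)
        _rhs_batch_kernel(states, self.alpha, self.delta, *self._term_args(), out)
        return out

    def _term_args(self):
        return (
            self.act_ptr,
            self.act_src,
            self.act_k,
            self.act_h,
            self.inh_ptr,
            self.inh_src,
            self.inh_k,
            self.inh_h,
            self.beta,
            self.pure_repression,
            self.num_add,
            self.den_add,
        )


def compile_model(
    topology: NetworkTopology,
    params: ParameterSet,
    active_inputs: Iterable[str] = (),
) -> CompiledModel:
    active = frozenset(active_inputs)
    nodes = topology.nodes
    n = len(nodes)
    idx = {name: i for i, name in enumerate(nodes)}

    act_ptr = np.zeros(n + 1, dtype=np.int64)
    inh_ptr = np.zeros(n + 1, dtype=np.int64)
    act_src, act_k, act_h = [], [], []
    inh_src, inh_k, inh_h = [], [], []
    beta = np.zeros(n)
    pure = np.zeros(n, dtype=np.bool_)
    num_add = np.zeros(n)
    den_add = np.zeros(n)

    for i, node in enumerate(nodes):
        for src in topology.activators_of(node):
            act_src.append(idx[src])
            act_k.append(params.k[(src, node)])
            act_h.append(params.h[(src, node)])
        act_ptr[i + 1] = len(act_src)
        for src in topology.inhibitors_of(node):
            inh_src.append(idx[src])
            inh_k.append(params.k[(src, node)])
            inh_h.append(params.h[(src, node)])
        inh_ptr[i + 1] = len(inh_src)
        if topology.has_beta(node):
            beta[i] = params.beta[node]
        else:
            pure[i] = True
        if topology.external_activator_of(node) in active:
            num_add[i] = params.beta_vascl1
        if topology.external_inhibitor_of(node) in active:
            den_add[i] = params.beta_resti

    return CompiledModel(
        nodes=nodes,
        alpha=np.array([params.alpha[n_] for n_ in nodes]),
        delta=np.array([params.delta[n_] for n_ in nodes]),
        act_ptr=act_ptr,
        act_src=np.array(act_src, dtype=np.int64),
        act_k=np.array(act_k, dtype=np.float64),
        act_h=np.array(act_h, dtype=np.float64),
        inh_ptr=inh_ptr,
        inh_src=np.array(inh_src, dtype=np.int64),
        inh_k=np.array(inh_k, dtype=np.float64),
        inh_h=np.array(inh_h, dtype=np.float64),
        beta=beta,
        pure_repression=pure,
        num_add=num_add,
        den_add=den_add,
    )


def active_inputs_for(stage_name: str) -> frozenset[str]:
    from .network import STAGE_INPUTS

    return STAGE_INPUTS[stage_name]


# ---------------------------------------------------------------------------
# Kernels


@njit(cache=True)
def _sa_kernel(
    state,
    act_ptr,
    act_src,
    act_k,
    act_h,
    inh_ptr,
    inh_src,
    inh_k,
    inh_h,
    beta,
    pure,
    num_add,
    den_add,
    out,
):
    n = state.shape[0]
    for i in range(n):
        s_act = 0.0
        for j in range(act_ptr[i], act_ptr[i + 1]):
            s_act += (state[act_src[j]] / act_k[j]) ** act_h[j]
        s_inh = 0.0
        for j in range(inh_ptr[i], inh_ptr[i + 1]):
            s_inh += (state[inh_src[j]] / inh_k[j]) ** inh_h[j]
        if pure[i]:
            out[i] = 1.0 / (1.0 + s_inh + den_add[i])
        else:
            num = beta[i] + s_act + num_add[i]
            out[i] = num / (1.0 + num + s_inh + den_add[i])


@njit(cache=True)
def _rhs_kernel(
    state,
    alpha,
    delta,
    act_ptr,
    act_src,
    act_k,
    act_h,
    inh_ptr,
    inh_src,
    inh_k,
    inh_h,
    beta,
    pure,
    num_add,
    den_add,
    out,
):
    _sa_kernel(
        state,
        act_ptr,
        act_src,
        act_k,
        act_h,
        inh_ptr,
        inh_src,
        inh_k,
        inh_h,
        beta,
        pure,
        num_add,
        den_add,
        out,
    )
    for i in range(state.shape[0]):
        out[i] = alpha[i] * out[i] - delta[i] * state[i]


@njit(cache=True)
def _rhs_batch_kernel(
    states,
    alpha,
    delta,
    act_ptr,
    act_src,
    act_k,
    act_h,
    inh_ptr,
    inh_src,
    inh_k,
    inh_h,
    beta,
    pure,
    num_add,
    den_add,
    out,
):
    for r in range(states.shape[0]):
        _rhs_kernel(states[r], alpha, delta, act_ptr, act_src, act_k, act_h,
                    inh_ptr, inh_src, inh_k, inh_h, beta, pure, num_add,
                    den_add, out[r])


@njit(cache=True)
def _rk4_kernel(
    y0,
    dt,
    n_steps,
    rem,
    alpha,
    delta,
    act_ptr,
    act_src,
    act_k,
    act_h,
    inh_ptr,
    inh_src,
    inh_k,
    inh_h,
    beta,
    pure,
    num_add,
    den_add,
    values,
):
    """Classic RK4 on a fixed grid; returns (clamp_count, fail_index).

    ``values`` must be pre-allocated with shape (n_points, n); row 0 is y0.
    fail_index = -1 on success, else the first row with a non-finite state.
    """
    n = y0.shape[0]
    y = y0.copy()
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    tmp = np.empty(n)
    clamps = 0
    values[0, :] = y
    total = n_steps + (1 if rem > 0.0 else 0)
    for step in range(total):
        hstep = dt if step < n_steps else rem
        _rhs_kernel(y, alpha, delta, act_ptr, act_src, act_k, act_h, inh_ptr,
                    inh_src, inh_k, inh_h, beta, pure, num_add, den_add, k1)
        for i in range(n):
            tmp[i] = y[i] + 0.5 * hstep * k1[i]
            if tmp[i] < 0.0:
                tmp[i] = 0.0
        _rhs_kernel(tmp, alpha, delta, act_ptr, act_src, act_k, act_h, inh_ptr,
                    inh_src, inh_k, inh_h, beta, pure, num_add, den_add, k2)
        for i in range(n):
            tmp[i] = y[i] + 0.5 * hstep * k2[i]
            if tmp[i] < 0.0:
                tmp[i] = 0.0
        _rhs_kernel(tmp, alpha, delta, act_ptr, act_src, act_k, act_h, inh_ptr,
                    inh_src, inh_k, inh_h, beta, pure, num_add, den_add, k3)
        for i in range(n):
            tmp[i] = y[i] + hstep * k3[i]
            if tmp[i] < 0.0:
                tmp[i] = 0.0
        _rhs_kernel(tmp, alpha, delta, act_ptr, act_src, act_k, act_h, inh_ptr,
                    inh_src, inh_k, inh_h, beta, pure, num_add, den_add, k4)
        ok = True
        for i in range(n):
            y[i] = y[i] + (hstep / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            if y[i] < 0.0:
                y[i] = 0.0
                clamps += 1
            if not np.isfinite(y[i]):
                ok = False
        values[step + 1, :] = y
        if not ok:
            return clamps, step + 1
    return clamps, -1


@njit(cache=True)
def _gillespie_kernel(
    y0,
    duration,
    eta,
    grid,
    alpha,
    delta,
    act_ptr,
    act_src,
    act_k,
    act_h,
    inh_ptr,
    inh_src,
    inh_k,
    inh_h,
    beta,
    pure,
    num_add,
    den_add,
    seed,
    max_events,
    values,
):
    """Direct-method SSA with per-node jump size eta[i].

    Two channels per node: production (+eta, rate alpha*SA/eta) and decay
    (-eta, rate delta*[X]/eta).  Propensities are recomputed after every
    event.  The trajectory is recorded on ``grid`` by last-value
    carry-forward.  Returns the number of events (negative if max_events
    was exceeded).
    """
    np.random.seed(seed)
    n = y0.shape[0]
    y = y0.copy()
    sa = np.empty(n)
    t = 0.0
    gi = 0
    n_grid = grid.shape[0]
    events = 0
    while True:
        _sa_kernel(y, act_ptr, act_src, act_k, act_h, inh_ptr, inh_src,
                   inh_k, inh_h, beta, pure, num_add, den_add, sa)
        total = 0.0
        for i in range(n):
            total += alpha[i] * sa[i] / eta[i] + delta[i] * y[i] / eta[i]
        if total <= 0.0:
            # frozen state: the remaining time elapses unchanged
            while gi < n_grid:
                values[gi, :] = y
                gi += 1
            return events
        tau = np.random.exponential(1.0 / total)
        t_next = t + tau
        while gi < n_grid and grid[gi] < t_next and grid[gi] <= duration:
            values[gi, :] = y
            gi += 1
        if t_next > duration:
            while gi < n_grid:
                values[gi, :] = y
                gi += 1
            return events
        u = np.random.random() * total
        acc = 0.0
        for i in range(n):
            acc += alpha[i] * sa[i] / eta[i]
            if u < acc:
                y[i] += eta[i]
                break
            acc += delta[i] * y[i] / eta[i]
            if u < acc:
                y[i] -= eta[i]
                if y[i] < 0.0:
                    y[i] = 0.0
                break
        t = t_next
        events += 1
        if events >= max_events:
            while gi < n_grid:
                values[gi, :] = y
                gi += 1
            return -events
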