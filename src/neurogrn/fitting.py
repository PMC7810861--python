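"""Objective function and real-valued genetic algorithm for parameter fitting.

The objective integrates the model three times — fibroblast, REST-knockdown
and conversion stages — and scores

    fitness = -(SSE + R1 + R2)

where SSE compares the simulated knockdown endpoint (72 h) and the first
five conversion days (8 h, 1, 2, 3, 5 d) against the per-factor medians of
the replicate observations; R1 = lambda * sum_X int_0^5d |f''| dt penalises
erratic oscillation of the conversion fit; and R2 = mu * sum_X int_0^3d
|f'| dt penalises any drift of the unperturbed fibroblast stage (fibroblasts
must not convert spontaneously).  lambda = mu = 1/20 by default.

The GA evolves a vector of positive reals, one per free parameter.  Hill
exponents are stored as unbounded raw genes h' and decoded as
h = 4 h'/(1 + h'), capping cooperativity at 4.  Mutation multiplies each
gene by three independent draws from m(2/n, 1.01) * m(2/(3n), 1.05) *
m(1/(5n), 1.5), where m(p, s) is 1 with probability 1 - p and otherwise
log-normal with geometric standard deviation s (fine, medium and coarse
multiplicative steps); crossover is uniform (per-gene exchange with
probability 1/2).  Selection and elitism are not dictated by the model:
tournament selection over a population whose top fraction survives each
generation (a mu+lambda scheme) keeps the best-ever fitness monotone and
lets the fine mutation component actually accumulate refinements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .deterministic import (
    DEFAULT_STEP_H,
    InitialPolicy,
    Trajectory,
    integrate_stage,
)
from .engine import IntegrationError, compile_model
from .network import (
    NetworkTopology,
    ParameterSet,
    STAGE_INPUTS,
    fibroblast_baseline,
)
from .synth import OBJECTIVE_ANCHORS, TimeSeriesDataset

WORST_FITNESS = -1.0e300

HILL_CAP = 4.0


def decode_hill(raw: float) -> float:
    """Map an unbounded positive raw gene to a Hill exponent in (0, 4)."""
    if raw <= 0:
        raise ValueError("raw Hill gene must be strictly positive")
    return HILL_CAP * raw / (1.0 + raw)


def encode_hill(h: float) -> float:
    """Inverse of :func:`decode_hill`, for seeding genomes from parameters."""
    if not 0 < h < HILL_CAP:
        raise ValueError(f"Hill exponent must lie in (0, {HILL_CAP})")
    return h / (HILL_CAP - h)


# ---------------------------------------------------------------------------
# Genome layout


def genome_spec(topology: NetworkTopology) -> tuple[tuple[str, object], ...]:
    """Ordered (kind, key) labels of the free parameters of a topology."""
    spec: list[tuple[str, object]] = []
    for n in topology.nodes:
        spec.append(("alpha", n))
    for n in topology.nodes:
        spec.append(("delta", n))
    for n in topology.beta_nodes:
        spec.append(("beta", n))
    for pair in sorted({(s, t) for s, t, _ in topology.edges}):
        spec.append(("k", pair))
        spec.append(("h_raw", pair))
    spec.append(("beta_RESTi", None))
    spec.append(("beta_vAscl1", None))
    return tuple(spec)


def decode_genome(genome: np.ndarray, topology: NetworkTopology) -> ParameterSet:
    spec = genome_spec(topology)
    if len(genome) != len(spec):
        raise ValueError(f"genome length {len(genome)} != {len(spec)} free parameters")
    if np.any(np.asarray(genome) <= 0):
        raise ValueError("genome values must be strictly positive")
    alpha, delta, beta = {}, {}, {}
    k, h = {}, {}
    beta_resti = beta_vascl1 = None
    for (kind, key), value in zip(spec, genome):
        v = float(value)
        if kind == "alpha":
            alpha[key] = v
        elif kind == "delta":
            delta[key] = v
        elif kind == "beta":
            beta[key] = v
        elif kind == "k":
            k[key] = v
        elif kind == "h_raw":
            h[key] = decode_hill(v)
        elif kind == "beta_RESTi":
            beta_resti = v
        elif kind == "beta_vAscl1":
            beta_vascl1 = v
    return ParameterSet(alpha, delta, beta, k, h, beta_resti, beta_vascl1)


def encode_params(params: ParameterSet, topology: NetworkTopology) -> np.ndarray:
    """Genome whose decoding reproduces ``params`` (h re-encoded as raw)."""
    out = []
    for kind, key in genome_spec(topology):
        if kind == "alpha":
            out.append(params.alpha[key])
        elif kind == "delta":
            out.append(params.delta[key])
        elif kind == "beta":
            out.append(params.beta[key])
        elif kind == "k":
            out.append(params.k[key])
        elif kind == "h_raw":
            out.append(encode_hill(params.h[key]))
        elif kind == "beta_RESTi":
            out.append(params.beta_resti)
        elif kind == "beta_vAscl1":
            out.append(params.beta_vascl1)
    return np.array(out, dtype=np.float64)


def embed_genome(
    genome: np.ndarray,
    from_topology: NetworkTopology,
    to_topology: NetworkTopology,
    background: float = 100.0,
) -> np.ndarray:
    """Map a fitted genome onto a richer topology as a near-equivalent start.

    Supports topologies that extend ``from_topology`` by added activation
    edges.  A pure-repression node that gains its first activator switches
    from the 1/(1 + S_inh) form to the background form; the embedding makes
    the new form numerically equivalent to the old one by setting the new
    background large (beta = ``background``) and rescaling the node's
    existing edge dissociation constants by background^(-1/h), while the new
    edge itself starts far from saturation (k large).  Used to seed fits of
    more complex models from fits of simpler ones.
    """
    from_spec = genome_spec(from_topology)
    by_key = dict(zip(from_spec, np.asarray(genome, dtype=np.float64)))
    newly_background = [
        n for n in to_topology.beta_nodes if not from_topology.has_beta(n)
    ]
    out = []
    for kind, key in genome_spec(to_topology):
        if (kind, key) in by_key:
            value = by_key[(kind, key)]
            if kind == "k" and key[1] in newly_background:
                # inhibitor terms must scale with the background so the
                # occupancy ratio is preserved: (T/k')^h = B * (T/k)^h
                h_here = decode_hill(by_key[("h_raw", key)])
                value = value * background ** (-1.0 / h_here)
            out.append(value)
        elif kind == "beta" and key in newly_background:
            out.append(background)
        elif kind == "k":
            out.append(50.0)  # new edge starts effectively silent
        elif kind == "h_raw":
            out.append(1.0)
        elif kind == "beta":
            out.append(0.5)
        else:
            raise ValueError(f"cannot embed parameter {(kind, key)}")
    return np.array(out, dtype=np.float64)


# ---------------------------------------------------------------------------
# Objective terms


def sse_term(
    trajectories: Mapping[str, Trajectory],
    dataset: TimeSeriesDataset,
    nodes: Sequence[str] | None = None,
) -> float:
    """Squared error at the knockdown endpoint plus the 5-day conversion anchors.

    The fibroblast stage contributes nothing here (it is covered by the
    stability penalty).
    """
    nodes = tuple(nodes or dataset.binding.keys())
    total = 0.0
    for node in nodes:
        for stage, t in dataset.objective_anchors:
            try:
                observed = dataset.node_median(node, stage, t)
            except KeyError as err:
                raise KeyError(f"missing anchor for {node}: ({stage}, {t} h)") from err
            simulated = trajectories[stage].at(t, node)
            total += (simulated - observed) ** 2
    return total


def smoothness_penalty(conversion: Trajectory, lam: float, horizon_h: float = 120.0) -> float:
    """lambda * sum_X int |d2 f/dt2| dt over the first five conversion days.

    Second derivatives by central differences on the integration grid
    (one-sided at the ends), integral by the trapezoid rule.
    """
    if lam == 0:
        return 0.0
    t = conversion.times
    if t[-1] + 1e-9 < horizon_h:
        raise ValueError(
            f"conversion trajectory covers only {t[-1]} h < {horizon_h} h"
        )
    mask = t <= horizon_h + 1e-9
    t = t[mask]
    total = 0.0
    for j in range(len(conversion.nodes)):
        f = conversion.values[mask, j]
        d2 = np.gradient(np.gradient(f, t, edge_order=2), t, edge_order=2)
        total += np.trapezoid(np.abs(d2), t)
    return float(lam * total)


def stability_penalty(
    fibroblast: Trajectory,
    mu: float,
    topology: NetworkTopology,
    params: ParameterSet,
) -> float:
    """mu * sum_X int_0^3d |df/dt| dt with the external inputs off.

    The derivative is the model right-hand side evaluated along the stored
    trajectory (not a finite difference), integrated by the trapezoid rule.
    """
    if fibroblast.stage and fibroblast.stage != "fibroblast":
        raise ValueError(
            "stability penalty must be evaluated on the input-free fibroblast stage"
        )
    if mu == 0:
        return 0.0
    model = compile_model(topology, params, active_inputs=())
    derivs = model.rhs_batch(fibroblast.values)
    total = 0.0
    for j in range(len(fibroblast.nodes)):
        total += np.trapezoid(np.abs(derivs[:, j]), fibroblast.times)
    return float(mu * total)


@dataclass(frozen=True)
class FitConfig:
    """GA and objective settings (population 100, uniform crossover)."""

    population: int = 100
    generations: int = 300
    lam: float = 1.0 / 20.0
    mu: float = 1.0 / 20.0
    tournament: int = 4
    elitism: int = 2
    cx_gene_rate: float = 0.5
    seed: int = 0
    seed_genomes: tuple = ()
    step_h: float = DEFAULT_STEP_H
    fibroblast_h: float = 72.0
    rest_kd_h: float = 72.0
    conversion_h: float = 120.0  # only the first 5 days enter the objective
    conversion_init: str = "observed"  # or "carry" from the knockdown stage

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be at least 2")
        if self.lam < 0 or self.mu < 0:
            raise ValueError("penalty weights must be non-negative")


def _objective_trajectories(
    topology: NetworkTopology,
    params: ParameterSet,
    dataset: TimeSeriesDataset,
    config: FitConfig,
) -> dict[str, Trajectory]:
    base = fibroblast_baseline(topology)
    out: dict[str, Trajectory] = {}
    model_f = compile_model(topology, params, STAGE_INPUTS["fibroblast"])
    out["fibroblast"] = integrate_stage(
        model_f, base, config.fibroblast_h, config.step_h, "fibroblast"
    )
    model_r = compile_model(topology, params, STAGE_INPUTS["rest_kd"])
    out["rest_kd"] = integrate_stage(
        model_r, base, config.rest_kd_h, config.step_h, "rest_kd"
    )
    if config.conversion_init == "observed":
        conv_init = dataset.observed_post_kd_state(topology.nodes)
    elif config.conversion_init == "carry":
        conv_init = out["rest_kd"].final_state()
    else:
        raise ValueError(f"unknown conversion_init {config.conversion_init!r}")
    model_c = compile_model(topology, params, STAGE_INPUTS["conversion"])
    out["conversion"] = integrate_stage(
        model_c, conv_init, config.conversion_h, config.step_h, "conversion"
    )
    return out


def objective_terms(
    params: ParameterSet,
    topology: NetworkTopology,
    dataset: TimeSeriesDataset,
    config: FitConfig,
) -> tuple[float, float, float]:
    """(SSE, R1, R2) for one parameter set."""
    trajs = _objective_trajectories(topology, params, dataset, config)
    sse = sse_term(trajs, dataset)
    r1 = smoothness_penalty(trajs["conversion"], config.lam)
    r2 = stability_penalty(trajs["fibroblast"], config.mu, topology, params)
    return sse, r1, r2


def fitness(
    genome: np.ndarray,
    topology: NetworkTopology,
    dataset: TimeSeriesDataset,
    config: FitConfig,
) -> float:
    """-(SSE + R1 + R2); non-finite simulations score the worst sentinel."""
    try:
        params = decode_genome(genome, topology)
        sse, r1, r2 = objective_terms(params, topology, dataset, config)
    except (IntegrationError, FloatingPointError, OverflowError, ValueError):
        return WORST_FITNESS
    value = -(sse + r1 + r2)
    if not np.isfinite(value):
        return WORST_FITNESS
    return float(value)


# ---------------------------------------------------------------------------
# GA operators


def _mixture_factors(n_genes: int, p: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    hit = rng.random(n_genes) < p
    factors = np.ones(n_genes)
    n_hit = int(hit.sum())
    if n_hit:
        factors[hit] = np.exp(rng.normal(0.0, sigma, size=n_hit))
    return factors


def mutate(genome: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Multiply each gene by m(2/n, 1.01) * m(2/(3n), 1.05) * m(1/(5n), 1.5).

    The second argument of each component is its geometric standard
    deviation: non-unit factors are exp(N(0, ln s)) — multiplicative steps
    of roughly 1%, 5% and 50%, a fine/medium/coarse ladder.
    """
    n = len(genome)
    out = genome.copy()
    for p, gsd in ((2.0 / n, 1.01), (2.0 / (3.0 * n), 1.05), (1.0 / (5.0 * n), 1.5)):
        out *= _mixture_factors(n, p, math.log(gsd), rng)
    return out


def uniform_crossover(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator, gene_rate: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    swap = rng.random(len(a)) < gene_rate
    child1 = np.where(swap, b, a)
    child2 = np.where(swap, a, b)
    return child1, child2


@dataclass
class GAResult:
    best_genome: np.ndarray
    best_params: ParameterSet
    best_fitness: float
    trace: np.ndarray  # best-ever fitness after each generation (index 0 = initial)
    config: FitConfig


def run_ga(
    topology: NetworkTopology,
    dataset: TimeSeriesDataset,
    config: FitConfig,
) -> GAResult:
    """Generational GA with uniform crossover, composite mutation, 1-elitism.

    The initial population draws genes uniformly from (0, 1); optional seed
    genomes (e.g. parameters fitted on a simpler topology) replace the first
    individuals.  Returns the best-ever genome and the per-generation
    best-fitness trace (monotone non-decreasing by elitism).
    """
    rng = np.random.default_rng(config.seed)
    n_genes = len(genome_spec(topology))
    pop = rng.uniform(1e-6, 1.0, size=(config.population, n_genes))
    for i, g in enumerate(config.seed_genomes[: config.population]):
        pop[i] = np.asarray(g, dtype=np.float64)

    def evaluate(p):
        return np.array([fitness(ind, topology, dataset, config) for ind in p])

    fits = evaluate(pop)
    best_i = int(np.argmax(fits))
    best_genome = pop[best_i].copy()
    best_fit = float(fits[best_i])
    trace = [best_fit]

    n_elite = max(1, min(config.elitism, config.population - 1))
    for _ in range(config.generations):
        new_pop = np.empty_like(pop)
        elite_idx = np.argsort(fits)[::-1][:n_elite]
        new_pop[:n_elite] = pop[elite_idx]
        filled = n_elite
        while filled < config.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, config.population, size=config.tournament)
                winner = contenders[np.argmax(fits[contenders])]
                parents.append(pop[winner])
            c1, c2 = uniform_crossover(parents[0], parents[1], rng, config.cx_gene_rate)
            for child in (c1, c2):
                if filled >= config.population:
                    break
                new_pop[filled] = mutate(child, rng)
                filled += 1
        child_fits = evaluate(new_pop[n_elite:])
        pop = new_pop
        fits = np.concatenate([fits[elite_idx], child_fits])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_genome = pop[gen_best].copy()
        trace.append(best_fit)

    return GAResult(
        best_genome=best_genome,
        best_params=decode_genome(best_genome, topology),
        best_fitness=best_fit,
        trace=np.array(trace),
        config=config,
    )
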