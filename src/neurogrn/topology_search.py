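"""Enumeration and comparative fitting of network-topology variants.

Model selection proceeds by adding interactions to the literature network
and refitting: every single edge addition among the four active nodes (PTB,
nPTB, RESTc, miRs; Ascl1 is downstream-only), selected two-edge variants,
and two literature-motivated families — miRs -> Ascl1 activation, and the
experimentally observed PTB/nPTB self-inhibitions.  Variants are compared
by raw best GA fitness over a shared budget; no complexity penalty is
applied (single additions change the parameter count identically).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .fitting import FitConfig, run_ga
from .network import (
    ACTIVATION,
    INHIBITION,
    NetworkTopology,
    TopologyError,
    literature_topology,
)
from .synth import TimeSeriesDataset

#: Nodes eligible for added interactions (endogenous Ascl1 is read-out only).
ACTIVE_NODES = ("PTB", "nPTB", "RESTc", "miRs")

_SIGN_GLYPH = {ACTIVATION: "->", INHIBITION: "-|"}
_GLYPH_SIGN = {v: k for k, v in _SIGN_GLYPH.items()}


def edge_label(source: str, target: str, sign: str) -> str:
    return f"{source} {_SIGN_GLYPH[sign]} {target}"


def parse_edge_label(label: str) -> tuple[str, str, str]:
    for glyph, sign in _GLYPH_SIGN.items():
        if f" {glyph} " in label:
            source, target = label.split(f" {glyph} ")
            return source.strip(), target.strip(), sign
    raise ValueError(f"cannot parse edge label {label!r}")


def enumerate_single_additions(
    base: NetworkTopology | None = None,
    nodes: Sequence[str] = ACTIVE_NODES,
) -> list[tuple[str, NetworkTopology]]:
    """All single-edge additions among ``nodes``, labelled and order-stable.

    Self-edges and second edges on an already-connected ordered pair are
    excluded; from the literature base this yields exactly 12 variants
    (12 free ordered pairs x 2 signs - 2 x 6 occupied pairs).
    """
    base = base or literature_topology()
    occupied = {(s, t) for s, t, _ in base.edges}
    out = []
    for src in nodes:
        for tgt in nodes:
            if src == tgt or (src, tgt) in occupied:
                continue
            for sign in (ACTIVATION, INHIBITION):
                out.append((edge_label(src, tgt, sign), base.with_edge(src, tgt, sign)))
    return out


#: Named two-edge variants of the comparison table.
PAIRED_VARIANT_EDGES: dict[str, tuple[tuple[str, str, str], ...]] = {
    "nPTB -> PTB + RESTc": (("nPTB", "PTB", ACTIVATION), ("nPTB", "RESTc", ACTIVATION)),
    "nPTB -> RESTc -> PTB": (("nPTB", "RESTc", ACTIVATION), ("RESTc", "PTB", ACTIVATION)),
    "RESTc -| nPTB -> PTB": (("RESTc", "nPTB", INHIBITION), ("nPTB", "PTB", ACTIVATION)),
}


def paired_addition_variants(
    base: NetworkTopology | None = None,
    pairs: Mapping[str, Sequence[tuple[str, str, str]]] | None = None,
) -> list[tuple[str, NetworkTopology]]:
    """Two-edge variants: the named table rows plus any user-specified pairs."""
    base = base or literature_topology()
    pairs = dict(pairs) if pairs is not None else dict(PAIRED_VARIANT_EDGES)
    out = []
    for label, edges in pairs.items():
        if len(edges) != len({(s, t) for s, t, _ in edges}):
            raise TopologyError(f"variant {label!r} repeats an edge pair")
        topo = base
        for src, tgt, sign in edges:
            topo = topo.with_edge(src, tgt, sign)
        out.append((label, topo))
    return out


@dataclass(frozen=True)
class VariantFamily:
    """A base topology plus added edges and optional literature-motivated blocks."""

    base: NetworkTopology
    added_edges: tuple[tuple[str, str, str], ...] = ()
    with_mirs_to_ascl1: bool = False
    with_ptb_nptb_inhibitions: bool = False

    def expand(self) -> NetworkTopology:
        topo = self.base
        if self.with_ptb_nptb_inhibitions:
            # observed self-repression requires relaxing the self-edge rule
            from dataclasses import replace

            topo = replace(
                topo,
                permitted_self=topo.permitted_self | {("PTB", "PTB"), ("nPTB", "nPTB")},
            )
            for src, tgt, sign in (
                ("PTB", "PTB", INHIBITION),
                ("nPTB", "nPTB", INHIBITION),
                ("nPTB", "PTB", INHIBITION),
            ):
                if not any((s, t) == (src, tgt) for s, t, _ in topo.edges):
                    topo = topo.with_edge(src, tgt, sign)
        if self.with_mirs_to_ascl1:
            topo = topo.with_edge("miRs", "Ascl1", ACTIVATION)
        for src, tgt, sign in self.added_edges:
            topo = topo.with_edge(src, tgt, sign)
        return topo


def edge_profile_seeds(
    embedded,
    topology: NetworkTopology,
    base: NetworkTopology,
    k_grid: Sequence[float] = (0.7, 1.0, 1.5, 2.2),
    h_raw_grid: Sequence[float] = (1.0, 3.0, 9.0),
    beta_grid: Sequence[float] = (0.05, 0.5),
):
    """Seed genomes scanning the parameters of the edges added over ``base``.

    ``embedded`` is a base-topology fit mapped into the variant's genome
    space (see :func:`neurogrn.fitting.embed_genome`); the scan varies the
    new edges' dissociation constant and Hill gene (jointly, one grid point
    per seed) and, where a target newly gained a background, its beta.
    """
    from .fitting import genome_spec

    spec = genome_spec(topology)
    new_pairs = {(s, t) for s, t, _ in topology.edges} - {
        (s, t) for s, t, _ in base.edges
    }
    new_beta = set(topology.beta_nodes) - set(base.beta_nodes)
    k_idx = [spec.index(("k", p)) for p in sorted(new_pairs)]
    h_idx = [spec.index(("h_raw", p)) for p in sorted(new_pairs)]
    b_idx = [spec.index(("beta", n)) for n in sorted(new_beta)]
    seeds = [embedded]
    import numpy as np

    for kv in k_grid:
        for hv in h_raw_grid:
            for bv in beta_grid if b_idx else (None,):
                g = np.array(embedded, dtype=float).copy()
                for i in k_idx:
                    g[i] = kv
                for i in h_idx:
                    g[i] = hv
                if bv is not None:
                    for i in b_idx:
                        g[i] = bv
                seeds.append(g)
    return tuple(seeds)


def compare_models(
    variants: Sequence[tuple[str, NetworkTopology]],
    dataset: TimeSeriesDataset,
    config: FitConfig,
    n_restarts: int = 3,
    keep_best: int | None = None,
    prefit: tuple[NetworkTopology, object] | None = None,
) -> pd.DataFrame:
    """Fit every variant ``n_restarts`` times and rank by best fitness.

    Restarts use distinct seeds derived from config.seed; all variants
    share the same seeds and GA budget so fitnesses are comparable.
    When ``prefit`` is given as (base topology, fitted genome), each
    variant's population is seeded from the embedded base fit plus an
    added-edge parameter scan — the protocol for comparing nested models
    at small budgets, where random-start convergence noise would otherwise
    dominate the topology signal.
    Returns a long frame (variant, restart, seed, fitness, best) sorted by
    each variant's best fitness; ``keep_best`` truncates the per-variant
    restarts retained (e.g. the three best fits).
    """
    from .fitting import embed_genome

    rows = []
    for label, topo in variants:
        seed_genomes = ()
        if prefit is not None:
            base_topo, base_genome = prefit
            if topo.edges == base_topo.edges:
                seed_genomes = (base_genome,)
            else:
                embedded = embed_genome(base_genome, base_topo, topo)
                seed_genomes = edge_profile_seeds(embedded, topo, base_topo)
        fits = []
        for r in range(n_restarts):
            seed = int(config.seed) + 7919 * r
            res = run_ga(
                topo,
                dataset,
                dataclasses.replace(config, seed=seed, seed_genomes=seed_genomes),
            )
            fits.append((r, seed, res.best_fitness))
        fits.sort(key=lambda x: -x[2])
        if keep_best is not None:
            fits = fits[:keep_best]
        best = fits[0][2]
        for r, seed, f in fits:
            rows.append(
                {"variant": label, "restart": r, "seed": seed, "fitness": f, "best": best}
            )
    frame = pd.DataFrame(rows)
    return frame.sort_values(["best", "variant", "fitness"], ascending=[False, True, False]).reset_index(
        drop=True
    )
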