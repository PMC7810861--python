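"""Rank every single-edge addition to the literature network.

Enumerates the 12 admissible single additions among PTB, nPTB, RESTc and
miRs (no self-edges, no second edge on an occupied pair) and fits each
variant plus the literature base with a shared budget.  All variants are
seeded from one literature pre-fit (embedded into each variant's parameter
space, with an added-edge scan), so the ranking measures what each edge
buys rather than random-start luck.

Expect additions that close a negative feedback loop onto PTB to lead:
the direct nPTB -> PTB activation (the generating edge), but also
nPTB -| miRs, which forms the indirect loop PTB -| nPTB -| miRs -| PTB and
can mimic the data's PTB dip-and-rebound.  Time-series fits alone cannot
separate such mechanistic alternatives — that is what the perturbation
grid (analysis 04) is for.  The scan is exploratory: at this reduced
budget, mid-field ordering reflects residual convergence noise.

Run:  python analysis/03_topology_scan.py [generations] [restarts] [seed]
"""

import sys
from pathlib import Path

from neurogrn import FitConfig, literature_topology, run_ga
from neurogrn.synth import load_dataset
from neurogrn.topology_search import compare_models, enumerate_single_additions

OUT = Path("results")


def main(generations: int = 60, restarts: int = 1, seed: int = 13) -> None:
    dataset = load_dataset(OUT / "dataset.csv")
    lit = literature_topology()
    pre = run_ga(lit, dataset, FitConfig(
        population=100, generations=generations, seed=seed, tournament=16, elitism=4))
    print(f"shared literature pre-fit: {pre.best_fitness:.4f}")

    variants = [("literature (base)", lit)] + enumerate_single_additions()
    config = FitConfig(population=100, generations=generations, seed=seed + 1,
                       tournament=16, elitism=4)
    ranking = compare_models(
        variants, dataset, config, n_restarts=restarts,
        prefit=(lit, pre.best_genome),
    )
    ranking.to_csv(OUT / "variant_ranking.csv", index=False)
    best_per_variant = ranking.groupby("variant", sort=False)["fitness"].max()
    print(best_per_variant.sort_values(ascending=False).to_string())
    print(f"\ntop variant: {best_per_variant.idxmax()}")


if __name__ == "__main__":
    gens = int(sys.argv[1]) if len(sys.argv) > 1 else 60
    restarts = int(sys.argv[2]) if len(sys.argv) > 2 else 1
    seed = int(sys.argv[3]) if len(sys.argv) > 3 else 13
    main(gens, restarts, seed)
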