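"""Overexpression/knockdown scenario grid plus the deep PTB-knockdown probe.

Runs the canonical eight scenarios (each: deterministic 14-day trajectory
from the fibroblast baseline plus 50 Gillespie replicates) on the
ground-truth nPTB -> PTB model and writes the outcome table.  Then probes
PTB knockdown at 1/5000 of its transcription rate with and without reducing
the constitutive RESTc background fivefold — the dissection-motivated
explanation for why PTB knockdown alone fails to convert in this model.

Run:  python analysis/04_scenario_grid.py [seed] [n_runs]
"""

import sys
from pathlib import Path

from neurogrn.configio import params_from_csv
from neurogrn.network import nptb_to_ptb_topology
from neurogrn.scenarios import canonical_grid, deep_ptb_kd_probe, scenario_table
from neurogrn.stochastic import NoiseConfig

OUT = Path("results")


def main(seed: int = 0, n_runs: int = 50) -> None:
    topology = nptb_to_ptb_topology()
    params = params_from_csv(OUT / "truth_params.csv", topology)
    table = scenario_table(
        topology, params, canonical_grid(), NoiseConfig(), base_seed=seed, n_runs=n_runs
    )
    table.to_csv(OUT / "scenario_table.csv", index=False)
    print(table.to_string(index=False))

    probe = deep_ptb_kd_probe(topology, params, base_seed=seed + 31, n_runs=n_runs)
    with open(OUT / "deep_ptb_kd_probe.txt", "w") as fh:
        for label, call in probe.items():
            line = (f"{label}: {'Yes' if call.converted else 'No'} "
                    f"({call.n_converted}/{call.n_runs} runs converted)")
            print(line)
            fh.write(line + "\n")


if __name__ == "__main__":
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
    n_runs = int(sys.argv[2]) if len(sys.argv) > 2 else 50
    main(seed, n_runs)
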