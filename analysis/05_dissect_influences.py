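"""Arrow dissection of the conversion-stage regulatory influences.

Decomposes every node's transcription rate along the conversion trajectory
into per-regulator activation/inhibition arrow lengths plus the decay arrow
(L_act - L_inh equals the realised Shea-Ackers activity at every instant),
and summarises which interactions dominate each node early (first 2 days)
versus late.  Writes the long-format profile under results/.

Run:  python analysis/05_dissect_influences.py
"""

from pathlib import Path

from neurogrn import canonical_protocol, run_protocol
from neurogrn.configio import params_from_csv
from neurogrn.dissection import dissect_trajectory
from neurogrn.network import nptb_to_ptb_topology

OUT = Path("results")


def main() -> None:
    topology = nptb_to_ptb_topology()
    params = params_from_csv(OUT / "truth_params.csv", topology)
    trajs = run_protocol(topology, params, canonical_protocol())
    profile = dissect_trajectory(trajs["conversion"], topology, params, stride=400)
    profile.to_csv(OUT / "dissection_conversion.csv", index=False)

    early = profile[(profile["time_h"] <= 48.0) & (profile["class"] != "decay")]
    share = (
        early.groupby(["node", "class", "regulator"])["length"].mean().reset_index()
    )
    print("mean arrow length per regulator over the first two conversion days:")
    for node, g in share.groupby("node"):
        print(f"  {node}:")
        for _, row in g.sort_values("length", ascending=False).iterrows():
            print(f"    {row['class']:3s} {row['regulator']:12s} {row['length']:.3f}")


if __name__ == "__main__":
    main()
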