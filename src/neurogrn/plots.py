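"""Static figure helpers: staged trajectories and stacked arrow profiles."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .deterministic import STAGE_ORDER, Trajectory


def plot_protocol(trajs: Mapping[str, Trajectory], nodes: Sequence[str] | None = None, ax=None):
    """Three-phase layout: one panel per stage, concentrations over time."""
    import matplotlib.pyplot as plt

    stages = [s for s in STAGE_ORDER if s in trajs]
    fig, axes = plt.subplots(
        1, len(stages), figsize=(4 * len(stages), 3), sharey=True,
        gridspec_kw={"width_ratios": [trajs[s].times[-1] or 1.0 for s in stages]},
    )
    axes = np.atleast_1d(axes)
    for ax_, stage in zip(axes, stages):
        traj = trajs[stage]
        for node in nodes or traj.nodes:
            ax_.plot(traj.times, traj.series(node), label=node)
        ax_.set_title(stage)
        ax_.set_xlabel("time (h)")
    axes[0].set_ylabel("relative mRNA level")
    axes[-1].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def plot_arrow_profile(profile: pd.DataFrame, node: str, ax=None):
    """Stacked activation (up) / inhibition and decay (down) arrow areas."""
    import matplotlib.pyplot as plt

    sub = profile[profile["node"] == node]
    times = np.sort(sub["time_h"].unique())
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    base_up = np.zeros(len(times))
    base_dn = np.zeros(len(times))
    for cls, sign in (("act", 1.0), ("inh", -1.0), ("decay", -1.0)):
        for regulator in sub[sub["class"] == cls]["regulator"].unique():
            series = (
                sub[(sub["class"] == cls) & (sub["regulator"] == regulator)]
                .set_index("time_h")["length"]
                .reindex(times)
                .fillna(0.0)
                .to_numpy()
            )
            if sign > 0:
                ax.fill_between(times, base_up, base_up + series, label=regulator, alpha=0.7)
                base_up = base_up + series
            else:
                ax.fill_between(times, base_dn, base_dn - series, label=regulator, alpha=0.7)
                base_dn = base_dn - series
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("arrow length (units of alpha)")
    ax.set_title(node)
    ax.legend(frameon=False, fontsize=7, ncol=2)
    return ax
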