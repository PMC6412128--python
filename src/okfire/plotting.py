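"""Optional plotting helpers (matplotlib imported lazily)."""

from __future__ import annotations

import numpy as np

from .inference import ChainSet
from .summaries import collision_density, firing_diff_density, point_estimates


def plot_summary(chains: ChainSet, path=None):
    """Panel figure: reconstructed profile, collision and firing-difference
    densities, in the usual triplet-report layout."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .model_core import SimConfig, average_profile

    fp, _ = point_estimates(chains)
    fig, axes = plt.subplots(2, 2, figsize=(10, 7))
    rng = np.random.default_rng(0)
    prof = average_profile(fp, chains.triplet, SimConfig(M=1024), rng)
    ax = axes[0, 0]
    ax.step(prof.box_starts, prof.values, where="post", color="tab:blue")
    for x in chains.triplet.positions:
        ax.axvline(x, ls="--", c="r", lw=0.8)
    ax.set_ylabel("F_ave")
    ax.set_title("reconstructed profile (posterior medians)")

    ax = axes[0, 1]
    for pair, color in (((0, 1), "tab:blue"), ((1, 2), "tab:red"), ((0, 2), "gold")):
        cd = collision_density(chains, pair)
        centers = 0.5 * (cd.edges[:-1] + cd.edges[1:])
        ax.plot(centers, cd.hist, color=color, label=f"{pair} ({100 * cd.realized_fraction:.0f}%)")
    ax.legend(fontsize=7)
    ax.set_title("collision densities")

    for ax, pair in ((axes[1, 0], (0, 1)), (axes[1, 1], (1, 2))):
        fd = firing_diff_density(chains, pair)
        if not fd.empty:
            ax.hist(fd.diffs / 1000.0, bins=60, density=True, color="tab:grey")
            ax.axvline(fd.threshold / 1000.0, c="b", lw=0.8)
            ax.axvline(-fd.threshold / 1000.0, c="b", lw=0.8)
        ax.set_title(f"t{pair[1] + 1} - t{pair[0] + 1} (krbp)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
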