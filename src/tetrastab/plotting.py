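"""Static figure export: distribution overlays and difference-map heatmaps.

Matplotlib is imported lazily so headless pipelines that never plot pay
no import cost; the Agg backend is forced for file output.
"""

from __future__ import annotations


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_distributions(distributions: dict, out_path, xlabel: str = "RMSD (Å)") -> None:
    """Overlay density histograms (one per system) with shared axes."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, dist in distributions.items():
        ax.stairs(dist.densities, dist.bin_edges, label=name, fill=False)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_difference_map(diff, out_path) -> None:
    """Residue-index heatmap of a contact difference matrix in [0, 1]."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5.5, 5))
    im = ax.imshow(diff.matrix, vmin=0.0, vmax=1.0, cmap="viridis", origin="lower")
    ax.set_xlabel("residue index")
    ax.set_ylabel("residue index")
    ax.set_title(f"|{diff.target_system} − {diff.reference_system}|", fontsize=10)
    fig.colorbar(im, ax=ax, label="|Δ contact|")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
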