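"""Basic figures: dynamics traces and chip-grid contour plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .category_game import DynamicsTrace
from .chip_projection import ChipGrid


def plot_trace(trace: DynamicsTrace, path=None):
    """Success rate, category count and synonym count over communications."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2), sharex=True)
    x = trace.comms_per_agent
    for ax, (ys, label) in zip(
        axes,
        [
            (trace.success_rate, "success rate"),
            (trace.n_categories, "linguistic categories"),
            (trace.n_synonyms, "synonymous terms"),
        ],
    ):
        ax.plot(x, ys)
        ax.set_xlabel("communications per agent")
        ax.set_ylabel(label)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def plot_chip_grid(grid: ChipGrid, path=None, title: str | None = None):
    """Contour plot of the 8 x 40 chromatic block of a chip grid."""
    g = grid.chromatic_grid()
    fig, ax = plt.subplots(figsize=(10, 2.6))
    cs = ax.contourf(range(g.shape[1]), range(1, g.shape[0] + 1), g, levels=10)
    fig.colorbar(cs, ax=ax, label=grid.normalisation)
    ax.invert_yaxis()  # lightest row on top, as on the WCS chart
    ax.set_xlabel("hue column")
    ax.set_ylabel("lightness row")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


__all__ = ["plot_trace", "plot_chip_grid"]
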