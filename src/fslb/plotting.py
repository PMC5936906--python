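"""Support-surface rendering: the white-to-red bootstrap heat map."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import LinearSegmentedColormap

from .inference import SupportSurface

__all__ = ["BP_CMAP", "bp_color", "render_heatmap"]

# Linear ramp: 0% bootstrap support is pure white, 100% pure red.
BP_CMAP = LinearSegmentedColormap.from_list("bp_white_red", ["#ffffff", "#ff0000"])


def bp_color(value: float) -> tuple[float, float, float]:
    """RGB for a bootstrap percentage on the white->red ramp."""
    if not 0.0 <= value <= 100.0:
        raise ValueError("bootstrap support must lie in [0, 100]")
    r, g, b, _ = BP_CMAP(value / 100.0)
    return (r, g, b)


def render_heatmap(surface: SupportSurface, path=None, ax=None):
    """Draw the surface; X = sites removed (thousands), Y = taxa removed.

    Undefined cells (clade intersection empty) are hatched.  Raises if the
    surface has no defined cell at all.
    """
    values = surface.values
    if np.all(np.isnan(values)):
        raise ValueError("surface has no defined cells")
    created = ax is None
    if created:
        fig, ax = plt.subplots(figsize=(1.0 + 0.5 * values.shape[1], 1.0 + 0.4 * values.shape[0]))
    else:
        fig = ax.figure

    masked = np.ma.masked_invalid(values)
    ax.imshow(masked, cmap=BP_CMAP, vmin=0.0, vmax=100.0, aspect="auto", interpolation="nearest")
    for (i, j), v in np.ndenumerate(values):
        if np.isnan(v):
            ax.add_patch(
                plt.Rectangle((j - 0.5, i - 0.5), 1, 1, fill=False, hatch="///", edgecolor="0.5")
            )
    ax.set_xticks(range(values.shape[1]))
    ax.set_xticklabels([f"{c / 1000:g}" for c in surface.col_labels])
    ax.set_yticks(range(values.shape[0]))
    ax.set_yticklabels([str(r) for r in surface.row_labels])
    ax.set_xlabel("Fast-evolving sites removed (thousands)")
    ax.set_ylabel("Long-branch taxa removed")
    ax.set_title(f"BP for {surface.clade_name} ({surface.n_replicates} replicates)")
    if path is not None:
        fig.tight_layout()
        fig.savefig(path, dpi=150)
    if created:
        plt.close(fig)
    return ax
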