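"""Figure exports: signed adjusted-p heatmaps and chord-style connectograms.

The heatmap renders the signed adjusted-p convention for group differences:
two-sided diverging bins at 0.05 and 0.1 — dark orange for KO > WT at
p_adj ≤ 0.05, light orange for 0.05 < p_adj ≤ 0.1, dark/light blue for the
WT > KO side, white elsewhere, light gray for pairs excluded from testing.

The chord diagram is a static approximation of a Circos-style connectogram:
nodes on a circle, ribbons drawn as Bézier chords with width proportional
to connection weight.  Visual parity with Circos is not a goal.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402
from matplotlib.colors import BoundaryNorm, ListedColormap  # noqa: E402
from matplotlib.path import Path as MplPath  # noqa: E402
from matplotlib.patches import PathPatch  # noqa: E402

__all__ = ["signed_p_heatmap", "chord_diagram"]


def signed_p_heatmap(signed_p: pd.DataFrame, path: str | Path,
                     title: str = "") -> Path:
    """Render a signed adjusted-p matrix with diverging bins at ±0.05/±0.1."""
    values = signed_p.to_numpy(dtype=float)
    cmap = ListedColormap([
        "#ffffff",  # p_adj > 0.1, WT > KO
        "#a6cee3",  # light blue: −0.1 ≤ signed ≤ −0.05
        "#1f4e9c",  # dark blue:  −0.05 < signed ≤ 0
        "#d95f02",  # dark orange: 0 < signed ≤ 0.05
        "#fdbf6f",  # light orange: 0.05 < signed ≤ 0.1
        "#ffffff",  # p_adj > 0.1, KO > WT
    ])
    norm = BoundaryNorm([-1.0, -0.1, -0.05, 0.0, 0.05, 0.1, 1.0], cmap.N)
    masked = np.ma.masked_invalid(values)
    n_rows, n_cols = values.shape
    fig, ax = plt.subplots(figsize=(max(6, n_cols * 0.22), max(5, n_rows * 0.22)))
    cmap.set_bad("#dddddd")
    im = ax.imshow(masked, cmap=cmap, norm=norm, interpolation="nearest")
    ax.set_xticks(range(n_cols), signed_p.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(n_rows), signed_p.index, fontsize=5)
    if title:
        ax.set_title(title, fontsize=9)
    cbar = fig.colorbar(im, ax=ax, shrink=0.6)
    cbar.set_label("signed FDR-adjusted p (+: KO > WT)", fontsize=7)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def chord_diagram(weights: pd.DataFrame, path: str | Path,
                  title: str = "", max_linewidth: float = 6.0) -> Path:
    """Chord-style connectogram of a labeled weight matrix."""
    w = weights.to_numpy(dtype=float)
    labels = list(weights.index)
    n = len(labels)
    theta = 2 * np.pi * np.arange(n) / n
    xy = np.column_stack([np.cos(theta), np.sin(theta)])
    colors = plt.cm.tab20(np.linspace(0, 1, n))
    fig, ax = plt.subplots(figsize=(8, 8))
    mx = w.max() if w.size and w.max() > 0 else 1.0
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] <= 0:
                continue
            verts = [tuple(xy[i]), (0.0, 0.0), tuple(xy[j])]
            patch = PathPatch(
                MplPath(verts, [MplPath.MOVETO, MplPath.CURVE3, MplPath.CURVE3]),
                fill=False, edgecolor=colors[i], alpha=0.6,
                linewidth=max(0.2, max_linewidth * w[i, j] / mx))
            ax.add_patch(patch)
    ax.scatter(xy[:, 0], xy[:, 1], s=40, c=colors, zorder=3)
    for i, lab in enumerate(labels):
        ang = np.degrees(theta[i])
        ha = "left" if np.cos(theta[i]) >= 0 else "right"
        ax.text(1.06 * xy[i, 0], 1.06 * xy[i, 1], lab, fontsize=6,
                ha=ha, va="center",
                rotation=ang if ha == "left" else ang - 180,
                rotation_mode="anchor")
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title, fontsize=10)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
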