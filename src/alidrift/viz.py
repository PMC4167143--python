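"""Render the similarity matrix as a color-coded heatmap and the tagged tree
with suspicious branches in red.

The palette anchors -1 at red, 0 at white and +1 at dark blue with linear
interpolation, so deep blue cells mark clearly non-random pairwise similarity
and red cells mark pairs indistinguishable from noise.  Missing (NaN) entries
are drawn gray.  Both renderers emit SVG.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LinearSegmentedColormap

from .similarity import SimilarityMatrix

#: -1 -> red, 0 -> white, +1 -> dark blue (linear in each channel per segment)
DEFAULT_ANCHORS = [(-1.0, "#d7191c"), (0.0, "#ffffff"), (1.0, "#08306b")]


def make_palette(anchors=None) -> LinearSegmentedColormap:
    """Colormap over [-1, 1] from (score, color) anchor points."""
    anchors = sorted(anchors or DEFAULT_ANCHORS)
    if anchors[0][0] != -1.0 or anchors[-1][0] != 1.0:
        raise ValueError("palette anchors must span exactly [-1, 1]")
    positions = [(s + 1) / 2 for s, _ in anchors]
    colors = [c for _, c in anchors]
    cmap = LinearSegmentedColormap.from_list("similarity", list(zip(positions, colors)))
    cmap.set_bad("#bdbdbd")
    return cmap


def render_heatmap(
    matrix: SimilarityMatrix,
    path,
    palette: LinearSegmentedColormap | None = None,
    order: list[str] | None = None,
) -> None:
    """Write an N x N colored-cell heatmap with taxon labels and a legend."""
    cmap = palette or make_palette()
    taxa = order or matrix.taxa
    idx = [matrix.index_of(t) for t in taxa]
    values = matrix.values[np.ix_(idx, idx)]
    n = len(taxa)

    size = max(3.5, 0.22 * n + 1.8)
    fig, ax = plt.subplots(figsize=(size + 1.2, size))
    im = ax.imshow(np.ma.masked_invalid(values), cmap=cmap, vmin=-1, vmax=1)
    ax.set_xticks(range(n), taxa, rotation=90, fontsize=7)
    ax.set_yticks(range(n), taxa, fontsize=7)
    cbar = fig.colorbar(im, ax=ax, fraction=0.04, pad=0.02)
    cbar.set_label("similarity score")
    cbar.set_ticks([-1, -0.5, 0, 0.5, 1])
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def _layout(tree):
    """Rectangular layout: leaf rows at integer y, x = cumulative branch length
    (unit edges when lengths are absent)."""
    xs, ys = {}, {}
    y = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ys[node] = y
            y += 1
        else:
            kids = node.child_nodes()
            ys[node] = (ys[kids[0]] + ys[kids[-1]]) / 2
    for node in tree.preorder_node_iter():
        parent_x = xs.get(node.parent_node, 0.0)
        el = node.edge.length if node.edge.length is not None else 1.0
        xs[node] = parent_x + (el if node.parent_node is not None else 0.0)
    return xs, ys


def render_tagged_tree(tree, reports, path) -> None:
    """Draw the annotated tree; suspicious branches stroked red, scores
    printed at each branch to 2 decimals."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    term = {r.branch_id: r for r in reports if r.kind == "terminal"}
    internal = {}
    for r in reports:
        if r.kind == "internal" and r.bipartition is not None:
            internal[r.bipartition] = r

    xs, ys = _layout(tree)
    n = len(leaves)
    fig, ax = plt.subplots(figsize=(8, max(2.5, 0.3 * n)))

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        report = None
        if node.is_leaf():
            report = term.get(node.taxon.label)
        else:
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            other = frozenset(leaves) - side
            if other and len(side) >= 2 and len(other) >= 2:
                from .treetag import Bipartition

                report = internal.get(Bipartition(side, other))
        color = "red" if (report is not None and report.suspicious) else "black"
        x0, x1 = xs[node.parent_node], xs[node]
        y0, y1 = ys[node.parent_node], ys[node]
        ax.plot([x0, x0], [y0, y1], color=color, lw=1.2)
        ax.plot([x0, x1], [y1, y1], color=color, lw=1.2)
        if report is not None:
            ax.text((x0 + x1) / 2, y1, f"{report.score:.2f}", fontsize=6,
                    color=color, va="bottom", ha="center")
        if node.is_leaf():
            ax.text(x1, y1, " " + node.taxon.label, fontsize=8, va="center")

    ax.set_axis_off()
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
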