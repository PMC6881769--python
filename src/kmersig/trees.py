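"""Species clustering from 1-CC distances.

The CC matrix is converted to a distance matrix d = 1 - CC and clustered
with UPGMA (arithmetic/size-weighted averaging), WPGMA (simple averaging)
or neighbor joining.  UPGMA/WPGMA produce rooted ultrametric trees; NJ an
unrooted tree with negative branch lengths clamped to zero.  Ties between
equally-distant cluster pairs are broken lexicographically so trees are
reproducible across runs and platforms.
"""

from __future__ import annotations

import io
from typing import Mapping

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from kmersig.correlation import CorrelationMatrix

__all__ = [
    "cc_to_distance",
    "upgma",
    "wpgma",
    "nj",
    "write_newick",
    "newick_string",
    "read_newick",
    "ordered_matrix",
    "is_ultrametric",
    "plot_heatmap",
]


def cc_to_distance(matrix: CorrelationMatrix) -> DistanceMatrix:
    """Elementwise 1 - CC with an exactly-zero diagonal."""
    values = 1.0 - matrix.values
    np.fill_diagonal(values, 0.0)
    values = np.maximum(values, 0.0)  # CC can round to 1+eps on re-read
    return DistanceMatrix(values, ids=list(matrix.species))


def _check_distance(dist: DistanceMatrix) -> None:
    if len(dist.ids) < 2:
        raise ValueError("need at least 2 species to build a tree")
    if (dist.data < 0).any():
        raise ValueError("distance matrix has negative entries")


def _agglomerate(dist: DistanceMatrix, weighted: bool) -> TreeNode:
    """UPGMA (weighted=False) / WPGMA (weighted=True) with lexicographic
    tie-breaking on the sorted leaf-label tuples of the candidate pair."""
    _check_distance(dist)
    ids = list(dist.ids)
    dd: dict[frozenset, float] = {}
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            dd[frozenset((a, ids[j]))] = float(dist[a, ids[j]])

    # cluster key -> (node, size, height, sorted leaf tuple)
    clusters: dict[str, tuple[TreeNode, int, float, tuple[str, ...]]] = {
        name: (TreeNode(name=name), 1, 0.0, (name,)) for name in ids
    }

    def pair_dist(a: str, b: str) -> float:
        return dd[frozenset((a, b))]

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                cand = (
                    pair_dist(a, b),
                    tuple(sorted(clusters[a][3] + clusters[b][3])),
                    a,
                    b,
                )
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, a, b = best
        node_a, size_a, h_a, leaves_a = clusters.pop(a)
        node_b, size_b, h_b, leaves_b = clusters.pop(b)
        height = pair_dist(a, b) / 2.0
        node_a.length = height - h_a
        node_b.length = height - h_b
        merged = TreeNode(children=[node_a, node_b])
        new_key = min(a, b)
        for other in list(clusters):
            if weighted:
                val = (pair_dist(a, other) + pair_dist(b, other)) / 2.0
            else:
                val = (
                    size_a * pair_dist(a, other) + size_b * pair_dist(b, other)
                ) / (size_a + size_b)
            dd[frozenset((new_key, other))] = val
        clusters[new_key] = (merged, size_a + size_b, height, tuple(sorted(leaves_a + leaves_b)))

    root = next(iter(clusters.values()))[0]
    root.length = None
    return root


def upgma(dist: DistanceMatrix) -> TreeNode:
    """Rooted ultrametric tree by unweighted (size-averaged) clustering."""
    return _agglomerate(dist, weighted=False)


def wpgma(dist: DistanceMatrix) -> TreeNode:
    """Rooted ultrametric tree by weighted (simple-average) clustering."""
    return _agglomerate(dist, weighted=True)


def nj(dist: DistanceMatrix) -> TreeNode:
    """Unrooted neighbor-joining tree (Q-criterion); negative branch
    lengths are clamped to zero."""
    _check_distance(dist)
    if len(dist.ids) == 2:
        a, b = dist.ids
        half = float(dist[a, b]) / 2.0
        return TreeNode(
            children=[TreeNode(name=a, length=half), TreeNode(name=b, length=half)]
        )
    return _skbio_nj(dist, neg_as_zero=True)


def _format_newick(node: TreeNode) -> str:
    if node.is_tip():
        body = node.name or ""
    else:
        body = "(" + ",".join(_format_newick(c) for c in node.children) + ")"
        if node.name:
            body += node.name
    if node.length is not None:
        body += f":{node.length:.6f}"
    return body


def newick_string(tree: TreeNode) -> str:
    """Newick with branch lengths at 6 decimals, no internal labels."""
    return _format_newick(tree) + ";"


def write_newick(tree: TreeNode, path) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")


def read_newick(path_or_text) -> TreeNode:
    if isinstance(path_or_text, str) and path_or_text.lstrip().startswith("("):
        return TreeNode.read(io.StringIO(path_or_text))
    return TreeNode.read(str(path_or_text))


def ordered_matrix(matrix: CorrelationMatrix, tree: TreeNode) -> CorrelationMatrix:
    """Permute the CC matrix rows/columns to the tree's leaf order
    (heatmap display order)."""
    leaves = [tip.name for tip in tree.tips()]
    if sorted(leaves) != sorted(matrix.species):
        raise ValueError("tree leaves do not match matrix species")
    idx = [matrix.species.index(name) for name in leaves]
    return CorrelationMatrix(
        species=leaves,
        values=matrix.values[np.ix_(idx, idx)],
        k=matrix.k,
        region_label=matrix.region_label,
    )


def is_ultrametric(tree: TreeNode, tol: float = 1e-9) -> bool:
    """True iff all root-to-tip path lengths agree within tol."""
    depths = [
        sum(n.length or 0.0 for n in tip.ancestors() if n.length is not None)
        + (tip.length or 0.0)
        for tip in tree.tips()
    ]
    return max(depths) - min(depths) <= tol


def plot_heatmap(matrix: CorrelationMatrix, path, cmap: str = "YlOrRd_r") -> None:
    """Render the (ordered) CC matrix as a PNG with a monotone color ramp."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(matrix.species)
    fig, ax = plt.subplots(figsize=(max(4, n * 0.3), max(4, n * 0.3)))
    im = ax.imshow(matrix.values, cmap=cmap, vmin=matrix.values.min(), vmax=1.0)
    ax.set_xticks(range(n))
    ax.set_yticks(range(n))
    ax.set_xticklabels(matrix.species, rotation=90, fontsize=6)
    ax.set_yticklabels(matrix.species, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson CC")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
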