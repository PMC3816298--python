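"""Trees of relatedness from profile matrices: clustering, cutting, export.

Profile vectors are compared with a configurable metric (Euclidean by
default) and merged by agglomerative hierarchical clustering (complete
linkage by default, matching the stock behaviour of the R ``hclust``/heatmap
pipeline this workflow mirrors). The merge loop is written here rather than
delegated so the tie-break is fully specified: among minimum-dissimilarity
candidate pairs, the pair with the smallest (i, j) cluster indices is merged,
giving bit-reproducible trees across platforms. The output uses the scipy
linkage-matrix convention, so scipy's tree-cutting utilities apply directly.

Clustering always operates on raw coverage proportions; the per-column
z-scaling offered by :func:`heatmap_export` is applied after the dendrogram
is computed and affects display only, never bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree
from scipy.spatial.distance import pdist, squareform

from .counting import ProfileMatrix

_METRIC_ALIASES = {
    "euclidean": "euclidean",
    "manhattan": "cityblock",
    "correlation": "correlation",
}
METRICS = tuple(_METRIC_ALIASES)
LINKAGES = ("complete", "average", "single")

ArrayLike = Union[ProfileMatrix, np.ndarray]


def _as_array(data: ArrayLike) -> np.ndarray:
    if isinstance(data, ProfileMatrix):
        return data.values
    return np.asarray(data, dtype=float)


def scipy_metric(metric: str) -> str:
    """Translate a public metric name to its scipy spelling."""
    try:
        return _METRIC_ALIASES[metric]
    except KeyError:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}") from None


def distance_matrix(data: ArrayLike, metric: str = "euclidean") -> np.ndarray:
    """Square symmetric distance matrix between profile rows.

    Raises on fewer than 2 rows, on rows containing NaN, and on distances
    that come out NaN (e.g. the correlation metric on a constant row).
    """
    X = _as_array(data)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("distance_matrix needs a 2-D array with at least 2 rows")
    if np.isnan(X).any():
        raise ValueError("profile rows contain NaN")
    D = squareform(pdist(X, metric=scipy_metric(metric)))
    if np.isnan(D).any():
        raise ValueError(
            f"{metric} distances are undefined for this input "
            "(constant rows have no correlation distance)"
        )
    return D


@dataclass
class Dendrogram:
    """Binary merge tree over labelled leaves.

    ``linkage`` follows the scipy convention: row t merges clusters with ids
    ``linkage[t, 0]`` and ``linkage[t, 1]`` (ids < n are leaves, id n+t is the
    cluster created at step t) at height ``linkage[t, 2]``, forming a cluster
    of ``linkage[t, 3]`` leaves.
    """

    labels: list[str]
    linkage: np.ndarray

    def __post_init__(self) -> None:
        self.linkage = np.asarray(self.linkage, dtype=float)
        n = len(self.labels)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError(
                f"linkage shape {self.linkage.shape} inconsistent with {n} leaves"
            )

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def _pair(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


def _agglomerate(dmat: np.ndarray, method: str) -> np.ndarray:
    """Deterministic agglomerative merge loop (Lance–Williams updates).

    O(n^3); intended for the desk-scale inputs this tool targets (tens to a
    few hundred sequences).
    """
    n = dmat.shape[0]
    dist: Dict[tuple[int, int], float] = {
        (i, j): float(dmat[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    Z = np.empty((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        # smallest distance, ties by smallest (i, j) cluster-id pair
        i, j = min(dist, key=lambda p: (dist[p], p))
        h = dist.pop((i, j))
        active.remove(i)
        active.remove(j)
        for k in active:
            a = dist.pop(_pair(i, k))
            b = dist.pop(_pair(j, k))
            if method == "complete":
                v = max(a, b)
            elif method == "single":
                v = min(a, b)
            else:  # average (UPGMA)
                v = (size[i] * a + size[j] * b) / (size[i] + size[j])
            dist[(k, next_id)] = v
        size[next_id] = size.pop(i) + size.pop(j)
        active.append(next_id)
        Z[step] = (i, j, h, size[next_id])
        next_id += 1
    return Z


def cluster(
    data: ArrayLike,
    metric: str = "euclidean",
    linkage: str = "complete",
    labels: Optional[list[str]] = None,
) -> Dendrogram:
    """Agglomeratively cluster profile rows into a dendrogram.

    Deterministic given row order; complete/average/single linkages are all
    monotone, which is asserted on every run.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    if labels is None:
        if isinstance(data, ProfileMatrix):
            labels = list(data.sequence_ids)
        else:
            labels = [str(i) for i in range(_as_array(data).shape[0])]
    D = distance_matrix(data, metric)
    Z = _agglomerate(D, linkage)
    heights = Z[:, 2]
    if not np.all(np.diff(heights) >= -1e-12):
        raise AssertionError("merge heights are not monotone non-decreasing")
    return Dendrogram(labels=labels, linkage=Z)


@dataclass
class BinAssignment:
    """Sequences grouped into k bins, with optional centroids and contrast.

    Bin labels are integers 1..k assigned by order of first appearance in the
    input row order. ``contrast`` is the mean silhouette width of the grouping
    (``None`` when undefined, e.g. k == 1).
    """

    labels: Dict[str, int]
    k: int
    set_name: Optional[str] = None
    centroids: Optional[Dict[int, np.ndarray]] = None
    contrast: Optional[float] = None

    def bins(self) -> Dict[int, list[str]]:
        out: Dict[int, list[str]] = {b: [] for b in range(1, self.k + 1)}
        for seq_id, b in self.labels.items():
            out[b].append(seq_id)
        return out


def cut(dendrogram: Dendrogram, k: int) -> BinAssignment:
    """Cut the tree into exactly k flat groups.

    The k-1 highest merges are undone (valid because heights are monotone);
    labels are renumbered 1..k by first appearance in input row order.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be between 1 and {n}, got {k}")
    raw = cut_tree(dendrogram.linkage, n_clusters=k).ravel()
    relabel: Dict[int, int] = {}
    for r in raw:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
    labels = {
        leaf: relabel[r] for leaf, r in zip(dendrogram.labels, raw)
    }
    return BinAssignment(labels=labels, k=k)


_NEWICK_UNSAFE = set(" ()[]{}:;,'\"\t\n")


def _newick_label(label: str) -> str:
    if set(label) & _NEWICK_UNSAFE or not label:
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(dendrogram: Dendrogram) -> str:
    """Serialise the dendrogram as a rooted ultrametric newick string.

    Leaves sit at height 0 and each merge at its linkage height; a child's
    branch length is half the height difference to its parent, so the
    cophenetic (leaf-to-leaf) path length through a node equals that node's
    merge height. Labels needing quoting are single-quoted per the newick
    standard.
    """
    n = dendrogram.n_leaves
    Z = dendrogram.linkage

    def height(node: int) -> float:
        return 0.0 if node < n else float(Z[node - n, 2])

    def render(node: int, parent_height: float) -> str:
        branch = (parent_height - height(node)) / 2.0
        if node < n:
            return f"{_newick_label(dendrogram.labels[node])}:{branch:.10g}"
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        h = height(node)
        return f"({render(left, h)},{render(right, h)}):{branch:.10g}"

    root = 2 * n - 2
    h = height(root)
    left, right = int(Z[root - n, 0]), int(Z[root - n, 1])
    return f"({render(left, h)},{render(right, h)});"


def compare_trees(newick_a: str, newick_b: str) -> int:
    """Unrooted Robinson–Foulds distance between two newick trees.

    The symmetric-difference count of non-trivial bipartitions: 0 iff the
    unrooted topologies are identical. Both trees must carry exactly the same
    leaf-label set.
    """
    import dendropy
    from dendropy.calculate import treecompare

    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    leaves1 = {leaf.taxon.label for leaf in t1.leaf_node_iter()}
    leaves2 = {leaf.taxon.label for leaf in t2.leaf_node_iter()}
    if leaves1 != leaves2:
        raise ValueError(
            "trees have different leaf sets; "
            f"only in first: {sorted(leaves1 - leaves2)}, "
            f"only in second: {sorted(leaves2 - leaves1)}"
        )
    return int(treecompare.symmetric_difference(t1, t2))


def monophyly_check(
    dendrogram: Dendrogram, groups: Mapping[str, Iterable[str]]
) -> Dict[str, bool]:
    """Which named leaf groups come out as clades when cutting at k=len(groups)?

    The desk-scale stand-in for comparing subtree arrangements against a
    reference taxonomy by eye: a group "forms a clade" iff it is exactly one
    of the k bins of the flat cut.
    """
    named = {name: frozenset(members) for name, members in groups.items()}
    covered = set().union(*named.values()) if named else set()
    if covered != set(dendrogram.labels):
        raise ValueError("groups must partition the dendrogram leaves")
    assignment = cut(dendrogram, k=len(named))
    bin_sets = {frozenset(members) for members in assignment.bins().values()}
    return {name: members in bin_sets for name, members in named.items()}


@dataclass
class HeatmapExport:
    """Profile matrix reordered to dendrogram leaf order, optionally z-scaled."""

    frame: pd.DataFrame
    row_order: list[str]
    col_order: list[str]
    scale: str

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", float_format="%.6g")

    def render(self, path, cmap: str = "viridis") -> None:
        """Write a heatmap image (requires matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(4.0, 0.12 * len(self.col_order)),
                     max(3.0, 0.3 * len(self.row_order)))
        )
        im = ax.imshow(self.frame.values, aspect="auto", cmap=cmap)
        ax.set_yticks(range(len(self.row_order)), labels=self.row_order, fontsize=7)
        ax.set_xticks([])
        fig.colorbar(im, ax=ax, shrink=0.7)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _leaf_order(dendrogram: Dendrogram) -> list[int]:
    n = dendrogram.n_leaves
    Z = dendrogram.linkage
    order: list[int] = []
    stack = [2 * n - 2]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
        else:
            left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
            stack.append(right)
            stack.append(left)
    return order


def heatmap_export(
    pm: ProfileMatrix, dendrogram: Dendrogram, scale: str = "none"
) -> HeatmapExport:
    """Reorder a profile matrix to a row dendrogram's leaf order for display.

    ``scale="column_z"`` standardises each motif column to mean 0, sd 1
    (columns with zero variance become all zeros). Scaling happens after
    clustering and is display-only.
    """
    if scale not in ("none", "column_z"):
        raise ValueError(f"scale must be 'none' or 'column_z', got {scale!r}")
    if set(dendrogram.labels) != set(pm.sequence_ids) or dendrogram.n_leaves != pm.n_sequences:
        raise ValueError("dendrogram leaves do not match profile matrix rows")
    order = [dendrogram.labels[i] for i in _leaf_order(dendrogram)]
    df = pm.to_dataframe().loc[order]
    if scale == "column_z":
        sd = df.std(axis=0, ddof=0)
        centered = df - df.mean(axis=0)
        df = centered.div(sd.where(sd > 0, 1.0), axis=1)
        df.loc[:, sd == 0] = 0.0
    return HeatmapExport(
        frame=df, row_order=order, col_order=list(df.columns), scale=scale
    )
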