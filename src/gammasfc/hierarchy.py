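"""Hierarchical agglomerative clustering of fused connectivity matrices.

The multi-scale representation of a connectome is a single dendrogram: nodes
(micro-regions) are agglomerated by WPGMA ("weighted") linkage on the
correlation distance between their connectivity rows.  Cutting the tree at M
modules yields a partition at that resolution; sweeping M traverses the scales.

Tree-level metrics quantify how modules live across scales:

* **MS** (module size) — number of leaves in a module at the reference cut.
* **MSI** (multi-scale index) — number of consecutive cut cardinalities at
  which a module persists intact, from the cut where it first appears as a
  module down to the cut at which it is absorbed into its parent.
* **H** (height) — the cut cardinality, counted from the top of the tree
  (M = 1), at which a leaf first stands alone as a singleton.
* **MH** (module height) — mean H over a module's members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import DegenerateNodeError, ParameterError, ValidationError

__all__ = [
    "MergeTree",
    "Partition",
    "TreeMetricsTable",
    "build_tree",
    "correlation_distance_matrix",
    "cut",
    "tree_metrics",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Partition:
    """Assignment of each node to exactly one module label."""

    node_ids: list[str]
    labels: list
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.node_ids) != len(self.labels):
            raise ValidationError(
                f"{len(self.node_ids)} node ids but {len(self.labels)} labels"
            )
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValidationError("duplicate node ids in partition")
        self._index = {n: l for n, l in zip(self.node_ids, self.labels)}

    @property
    def m(self) -> int:
        """Number of distinct modules."""
        return len(set(self.labels))

    def label_of(self, node_id: str):
        return self._index[node_id]

    def modules(self) -> dict:
        """Mapping module label -> list of member node ids (leaf order)."""
        out: dict = {}
        for n, l in zip(self.node_ids, self.labels):
            out.setdefault(l, []).append(n)
        return out

    def member_indices(self) -> dict:
        """Mapping module label -> numpy array of member positions."""
        out: dict = {}
        for i, l in enumerate(self.labels):
            out.setdefault(l, []).append(i)
        return {l: np.asarray(ix, dtype=int) for l, ix in out.items()}


@dataclass
class MergeTree:
    """Agglomerative dendrogram as an ordered merge table over N leaves.

    ``merges`` follows the scipy linkage convention: row k joins clusters
    ``left`` and ``right`` (ids 0..N-1 are leaves, id N+k is the cluster
    created by row k) at ``distance``, producing a cluster of ``size`` leaves.
    """

    leaf_ids: list[str]
    merges: np.ndarray  # (N-1, 4): left, right, distance, size

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        n = self.n_leaves
        if self.merges.shape != (n - 1, 4):
            raise ValidationError(
                f"merge table shape {self.merges.shape} for {n} leaves"
            )
        d = self.merges[:, 2]
        if np.any(np.diff(d) < -1e-12):
            raise ValidationError("merge distances are not non-decreasing")
        sizes = np.ones(2 * n - 1)
        for k, (a, b, _, s) in enumerate(self.merges):
            expected = sizes[int(a)] + sizes[int(b)]
            if expected != s:
                raise ValidationError(
                    f"merge {k}: recorded size {s} != child sizes {expected}"
                )
            sizes[n + k] = s
        if self.merges[-1, 3] != n:
            raise ValidationError("final merge does not cover all leaves")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)


@dataclass
class TreeMetricsTable:
    """MS/MSI/MH per module and H per leaf, at one reference cut."""

    reference_m: int
    module_table: pd.DataFrame  # index: module label; columns: ms, msi, mh
    leaf_heights: pd.Series  # index: leaf id; values: H


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------

def _extract_matrix(mat) -> tuple[np.ndarray, list[str]]:
    """Accept any container exposing .values and .node_ids (or leaf_ids)."""
    if isinstance(mat, np.ndarray):
        values = mat
        node_ids = [str(i) for i in range(mat.shape[0])]
    else:
        values = np.asarray(mat.values, dtype=float)
        node_ids = list(getattr(mat, "node_ids", getattr(mat, "leaf_ids", [])))
    return values, node_ids


def correlation_distance_matrix(
    values: np.ndarray,
    node_ids: list[str] | None = None,
    exclude_self: bool = False,
) -> np.ndarray:
    """Pairwise d(i,j) = 1 - Pearson(row_i, row_j) over connectivity rows.

    By default the full rows enter the correlation (including columns i and j,
    whose diagonal entries are zero).  With ``exclude_self=True`` columns i
    and j are dropped for the pair (i, j).

    Raises :class:`DegenerateNodeError` for any constant row, naming the node.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    ids = node_ids if node_ids is not None else [str(i) for i in range(n)]
    ptp = values.max(axis=1) - values.min(axis=1)
    bad = np.where(ptp == 0)[0]
    if bad.size:
        raise DegenerateNodeError(
            f"node {ids[bad[0]]!r} has a constant connectivity row; "
            "correlation distance is undefined"
        )
    if not exclude_self:
        r = np.corrcoef(values)
        d = 1.0 - r
    else:
        d = np.zeros((n, n))
        cols = np.arange(n)
        for i in range(n):
            for j in range(i + 1, n):
                keep = (cols != i) & (cols != j)
                xi, xj = values[i, keep], values[j, keep]
                if xi.std() == 0 or xj.std() == 0:
                    raise DegenerateNodeError(
                        f"pair ({ids[i]!r}, {ids[j]!r}) has a constant row "
                        "after dropping self-columns"
                    )
                d[i, j] = d[j, i] = 1.0 - np.corrcoef(xi, xj)[0, 1]
    np.fill_diagonal(d, 0.0)
    # 1 - r can dip below 0 by rounding when r ~ 1
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


def build_tree(fused, exclude_self: bool = False) -> MergeTree:
    """Agglomerate a connectivity matrix into a WPGMA dendrogram.

    Dissimilarity is the correlation distance between connectivity rows;
    linkage is WPGMA (scipy's ``weighted`` method), under which merge heights
    are monotone non-decreasing.
    """
    values, node_ids = _extract_matrix(fused)
    if values.shape[0] < 2:
        raise ParameterError("need at least 2 nodes to build a tree")
    d = correlation_distance_matrix(values, node_ids, exclude_self=exclude_self)
    z = linkage(squareform(d, checks=False), method="weighted")
    # guard against negligible non-monotonicity from floating point
    z[:, 2] = np.maximum.accumulate(z[:, 2])
    return MergeTree(leaf_ids=node_ids, merges=z)


# ---------------------------------------------------------------------------
# cutting
# ---------------------------------------------------------------------------

def _alive_clusters_after(tree: MergeTree, n_merges: int) -> list[int]:
    """Cluster ids present after applying the first ``n_merges`` merges."""
    n = tree.n_leaves
    alive = set(range(n))
    for k in range(n_merges):
        a, b = int(tree.merges[k, 0]), int(tree.merges[k, 1])
        alive.discard(a)
        alive.discard(b)
        alive.add(n + k)
    return sorted(alive)


def _leaves_of(tree: MergeTree, cluster: int) -> list[int]:
    """Leaf indices under a cluster id, in leaf order."""
    n = tree.n_leaves
    stack, leaves = [cluster], []
    while stack:
        c = stack.pop()
        if c < n:
            leaves.append(c)
        else:
            k = c - n
            stack.append(int(tree.merges[k, 0]))
            stack.append(int(tree.merges[k, 1]))
    return sorted(leaves)


def cut(tree: MergeTree, m: int) -> Partition:
    """Partition the leaves into exactly ``m`` modules.

    The cut applies the first N - m merges, so successive cuts are nested
    refinements (cut(m) refines cut(m-1) by splitting exactly one module)
    even when merge heights are tied.  Modules are labelled 1..m in order of
    their first member along the leaf list.
    """
    n = tree.n_leaves
    if not (1 <= m <= n):
        raise ParameterError(f"m={m} outside [1, {n}]")
    alive = _alive_clusters_after(tree, n - m)
    leaf_cluster = np.empty(n, dtype=int)
    for c in alive:
        leaf_cluster[_leaves_of(tree, c)] = c
    labels_raw = leaf_cluster.tolist()
    relabel: dict[int, int] = {}
    for c in labels_raw:
        if c not in relabel:
            relabel[c] = len(relabel) + 1
    return Partition(node_ids=list(tree.leaf_ids), labels=[relabel[c] for c in labels_raw])


# ---------------------------------------------------------------------------
# tree metrics
# ---------------------------------------------------------------------------

def tree_metrics(
    tree: MergeTree,
    reference_m: int,
    h_direction: str = "top_down",
    msi_mode: str = "levels",
) -> TreeMetricsTable:
    """MS, MSI and MH per module of the reference cut, plus H per leaf.

    ``h_direction='top_down'`` (default) counts H as the cut cardinality,
    starting from M = 1 at the root, at which the leaf first becomes a
    singleton; ``'bottom_up'`` counts levels from the bottom of the tree
    instead (H_bottom = N + 1 - H_top).

    ``msi_mode='levels'`` (default) counts cut cardinalities a module
    survives; ``'distance'`` reports the merge-distance interval between the
    module's creation and its absorption into its parent.
    """
    if h_direction not in ("top_down", "bottom_up"):
        raise ParameterError(f"unknown h_direction {h_direction!r}")
    if msi_mode not in ("levels", "distance"):
        raise ParameterError(f"unknown msi_mode {msi_mode!r}")

    n = tree.n_leaves
    part = cut(tree, reference_m)
    merges = tree.merges

    # absorbing merge (1-based) of every cluster id
    absorbed_at = {}
    for k in range(n - 1):
        absorbed_at[int(merges[k, 0])] = k + 1
        absorbed_at[int(merges[k, 1])] = k + 1

    # H per leaf: first merge that touches the leaf directly
    first_touch = np.array([absorbed_at[i] for i in range(n)])
    h_top = n - first_touch + 1
    h = h_top if h_direction == "top_down" else first_touch
    leaf_heights = pd.Series(h, index=list(tree.leaf_ids), name="H")

    alive = _alive_clusters_after(tree, n - reference_m)
    # map cluster -> module label of the reference partition
    cluster_label = {}
    for c in alive:
        cluster_label[c] = part.labels[_leaves_of(tree, c)[0]]

    rows = []
    for c in alive:
        leaves = _leaves_of(tree, c)
        birth = 0 if c < n else c - n + 1  # creating merge, 1-based
        death = absorbed_at.get(c)  # None only for the root cluster
        if msi_mode == "levels":
            msi = float(death - birth + 1) if death is not None else 1.0
        else:
            birth_d = 0.0 if c < n else merges[c - n, 2]
            death_d = merges[death - 1, 2] if death is not None else birth_d
            msi = death_d - birth_d
        rows.append(
            {
                "module": cluster_label[c],
                "ms": len(leaves),
                "msi": msi,
                "mh": float(np.mean(h[leaves])),
            }
        )
    module_table = (
        pd.DataFrame(rows).set_index("module").sort_index()[["ms", "msi", "mh"]]
    )
    return TreeMetricsTable(
        reference_m=reference_m, module_table=module_table, leaf_heights=leaf_heights
    )
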