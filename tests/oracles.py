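"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a pipeline quantity by direct enumeration (sorting,
pair counting, set intersection, naive agglomeration) without touching the
library's own code paths, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np


def median_oracle(stack: np.ndarray) -> np.ndarray:
    """Entry-wise median by explicit sorting of each link's subject vector."""
    n_subj, n, _ = stack.shape
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            vals = sorted(stack[s, i, j] for s in range(n_subj))
            k = n_subj // 2
            out[i, j] = vals[k] if n_subj % 2 else (vals[k - 1] + vals[k]) / 2.0
    return out


def modularity_oracle(adj: np.ndarray, labels) -> float:
    """Newman-Girvan Q by counting edges and degrees per module."""
    labels = list(labels)
    n = adj.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if adj[i, j] > 0]
    l_tot = len(edges)
    q = 0.0
    for c in set(labels):
        members = {i for i in range(n) if labels[i] == c}
        l_c = sum(1 for i, j in edges if i in members and j in members)
        d_c = sum(1 for i, j in edges for end in (i, j) if end in members)
        q += l_c / l_tot - (d_c / (2 * l_tot)) ** 2
    return q


def dice_oracle(a, b) -> float:
    a, b = set(a), set(b)
    inter = len([x for x in a if x in b])
    return 2.0 * inter / (len(a) + len(b))


def t_fs_link_oracle(fc: np.ndarray, sc: np.ndarray, labels) -> float:
    """Mean over modules of DICE between intra-module link sets."""
    labels = list(labels)
    n = fc.shape[0]
    scores = []
    for c in set(labels):
        members = [i for i in range(n) if labels[i] == c]
        fc_links = {
            (i, j) for i in members for j in members if i < j and fc[i, j] > 0
        }
        sc_links = {
            (i, j) for i in members for j in members if i < j and sc[i, j] > 0
        }
        if not fc_links and not sc_links:
            continue
        scores.append(dice_oracle(fc_links, sc_links))
    return float(np.mean(scores)) if scores else 0.0


def segregation_oracle(values: np.ndarray, labels, module) -> float:
    """Mean intra-module weight by explicit enumeration of ordered pairs."""
    labels = list(labels)
    members = [i for i in range(len(labels)) if labels[i] == module]
    total, count = 0.0, 0
    for i in members:
        for j in members:
            if i != j:
                total += values[i, j]
                count += 1
    return total / count


def overlap_fraction_oracle(part_labels, atlas_labels, module, atlas_label) -> float:
    members = {i for i, l in enumerate(part_labels) if l == module}
    in_label = {i for i, l in enumerate(atlas_labels) if l == atlas_label}
    return len(members & in_label) / len(members)


def wpgma_oracle(d: np.ndarray) -> np.ndarray:
    """Naive O(N^3) WPGMA agglomerator, scipy merge-table convention.

    At each step the globally closest active cluster pair merges (ties broken
    by the smallest (id, id) pair); distances to the merged cluster are the
    unweighted average of the children's distances.
    """
    n = d.shape[0]
    dist = {(i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    merges = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                a, b = active[ai], active[aj]
                key = (min(a, b), max(a, b))
                cand = (dist[key], key)
                if best is None or cand < best:
                    best = cand
        dval, (a, b) = best
        new = next_id
        next_id += 1
        sizes[new] = sizes[a] + sizes[b]
        merges.append([a, b, dval, sizes[new]])
        active = [c for c in active if c not in (a, b)]
        for c in active:
            ka = (min(a, c), max(a, c))
            kb = (min(b, c), max(b, c))
            dist[(min(new, c), max(new, c))] = (dist[ka] + dist[kb]) / 2.0
        active.append(new)
    return np.asarray(merges, dtype=float)


def studentized_flag_probability(m: int, threshold: float) -> float:
    """Exact P(|z| > threshold) for an internally studentized residual.

    For x_1..x_m iid normal and z_i = (x_i - mean) / sd (ddof = 1),
    z_i^2 * m / (m-1)^2 follows Beta(1/2, (m-2)/2).
    """
    from scipy import stats

    arg = threshold**2 * m / (m - 1) ** 2
    if arg >= 1.0:
        return 0.0
    return float(stats.beta(0.5, (m - 2) / 2.0).sf(arg))
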