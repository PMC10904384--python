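"""Cross-modularity: the objective that selects the optimal (gamma, M).

For a candidate partition (a cut of the gamma-fused tree) three qualities are
combined: Newman-Girvan modularity of the binary functional matrix (Q_F),
modularity of the binary structural matrix (Q_S) — both evaluated on the SAME
fused-tree partition — and the structure-function module similarity (T_FS).
Their geometric mean

    chi = (Q_F * Q_S * T_FS) ** (1/3)

is maximized jointly over the gamma grid and the module count M.  A partition
scores high only when it is simultaneously modular in both modalities and the
intra-module link patterns agree between them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    EmptyGraphError,
    GammaSFCError,
    ParameterError,
    UndefinedDiceError,
    ValidationError,
)
from .fusion import DEFAULT_GAMMA_GRID, FusedMatrix, fuse
from .hierarchy import MergeTree, Partition, build_tree, cut
from .io import ConnectivityMatrix
from .population import PopulationPair

logger = logging.getLogger("gammasfc")

__all__ = ["CrossModularityGrid", "modularity", "dice", "t_fs", "chi", "optimize"]


# ---------------------------------------------------------------------------
# components
# ---------------------------------------------------------------------------

def modularity(adj: ConnectivityMatrix, p: Partition) -> float:
    """Newman-Girvan modularity of a binary graph under a fixed partition.

    Q = sum_c [ L_c / L - (d_c / 2L)^2 ] with L the total link count, L_c the
    intra-module link count of module c and d_c its total degree.  Q lies in
    [-0.5, 1]; the single-module partition scores exactly 0.
    """
    if not adj.is_binary():
        raise ValidationError("modularity expects a binary matrix")
    a = adj.values
    two_l = a.sum()  # = 2L for a symmetric matrix with zero diagonal
    if two_l == 0:
        raise EmptyGraphError("modularity undefined on a graph without links")
    try:
        labels = np.asarray([p.label_of(n) for n in adj.node_ids])
    except KeyError as exc:
        raise ValidationError(f"partition does not cover node {exc}") from exc
    degrees = a.sum(axis=1)
    q = 0.0
    for lab in set(labels.tolist()):
        ix = np.where(labels == lab)[0]
        l_c = a[np.ix_(ix, ix)].sum() / 2.0
        d_c = degrees[ix].sum()
        q += l_c / (two_l / 2.0) - (d_c / two_l) ** 2
    return float(q)


def dice(a, b) -> float:
    """DICE similarity 2|a & b| / (|a| + |b|) of two sets."""
    a, b = set(a), set(b)
    if not a and not b:
        raise UndefinedDiceError("DICE of two empty sets is undefined")
    return 2.0 * len(a & b) / (len(a) + len(b))


def _intra_link_set(values: np.ndarray, ix: np.ndarray) -> set:
    """Linked (i, j) node-index pairs, i < j, inside one module."""
    sub = values[np.ix_(ix, ix)]
    iu = np.triu_indices(len(ix), k=1)
    present = sub[iu] > 0
    return {
        (int(ix[i]), int(ix[j]))
        for i, j, keep in zip(iu[0], iu[1], present)
        if keep
    }


def t_fs(pair: PopulationPair, p: Partition, strategy: str = "link-dice") -> float:
    """Structure-function module similarity for a partition.

    ``link-dice`` (default): for each module, DICE between its intra-module
    link sets in the binary FC and SC matrices, averaged over modules.
    Modules without intra-links in either matrix are excluded from the mean
    (0 if every module is excluded).  This stays informative when FC and SC
    share one partition, where node-set DICE would be trivially 1.

    ``node-dice`` (legacy): build separate FC and SC trees, cut both at the
    partition's module count, and average over functional modules the maximum
    node-set DICE against any structural module.  Note this variant does not
    depend on the fused partition, hence not on gamma.
    """
    if strategy not in ("link-dice", "node-dice"):
        raise ParameterError(f"unknown t_fs strategy {strategy!r}")
    if strategy == "link-dice":
        try:
            labels = np.asarray([p.label_of(n) for n in pair.node_ids])
        except KeyError as exc:
            raise ValidationError(f"partition does not cover node {exc}") from exc
        fc, sc = pair.fc_bin.values, pair.sc_bin.values
        scores = []
        for lab in set(labels.tolist()):
            ix = np.where(labels == lab)[0]
            fc_links = _intra_link_set(fc, ix)
            sc_links = _intra_link_set(sc, ix)
            if not fc_links and not sc_links:
                continue
            scores.append(dice(fc_links, sc_links))
        return float(np.mean(scores)) if scores else 0.0

    m = p.m
    fc_part = cut(build_tree(pair.fc_bin), m)
    sc_part = cut(build_tree(pair.sc_bin), m)
    sc_modules = [set(v) for v in sc_part.modules().values()]
    scores = [
        max(dice(set(fc_nodes), s) for s in sc_modules)
        for fc_nodes in fc_part.modules().values()
    ]
    return float(np.mean(scores))


def chi(q_f: float, q_s: float, t: float) -> float:
    """Cube root of Q_F * Q_S * T_FS; NaN when any factor is negative."""
    if q_f < 0 or q_s < 0 or t < 0:
        logger.debug(
            "chi undefined for negative factor(s): q_f=%.4g q_s=%.4g t=%.4g",
            q_f, q_s, t,
        )
        return float("nan")
    return float(np.cbrt(q_f * q_s * t))


# ---------------------------------------------------------------------------
# joint (gamma, M) search
# ---------------------------------------------------------------------------

@dataclass
class CrossModularityGrid:
    """chi and its three factors over the (gamma, M) grid, with the optimum."""

    gammas: list[float]
    module_counts: list[int]
    q_f: np.ndarray  # (n_gamma, n_m)
    q_s: np.ndarray
    t_fs: np.ndarray
    chi: np.ndarray
    valid_module_counts: np.ndarray  # modules with >= min_module_size leaves
    min_module_size: int
    optimum: tuple[float, int, float]  # (gamma*, M*, chi*)
    optimum_partition: Partition
    optimum_tree: MergeTree

    @property
    def n_valid_modules_at_optimum(self) -> int:
        gi = self.gammas.index(self.optimum[0])
        mi = self.module_counts.index(self.optimum[1])
        return int(self.valid_module_counts[gi, mi])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: gamma, m, q_f, q_s, t_fs, chi, n_valid_modules."""
        rows = []
        for gi, g in enumerate(self.gammas):
            for mi, m in enumerate(self.module_counts):
                rows.append(
                    {
                        "gamma": g,
                        "m": m,
                        "q_f": self.q_f[gi, mi],
                        "q_s": self.q_s[gi, mi],
                        "t_fs": self.t_fs[gi, mi],
                        "chi": self.chi[gi, mi],
                        "n_valid_modules": int(self.valid_module_counts[gi, mi]),
                    }
                )
        return pd.DataFrame(rows)


def optimize(
    pair: PopulationPair,
    gammas: list[float] | tuple[float, ...] = DEFAULT_GAMMA_GRID,
    m_range=None,
    min_module_size: int = 3,
    t_fs_strategy: str = "link-dice",
    exclude_self: bool = False,
) -> CrossModularityGrid:
    """Sweep (gamma, M), computing chi for every cell, and locate its maximum.

    For each gamma the pair is fused and one tree is built; every cut M in
    ``m_range`` (default 2..min(120, N)) yields a partition on which Q_F,
    Q_S (on fc_bin / sc_bin) and T_FS are evaluated.  Cells where chi is
    undefined (negative factor) are excluded from the maximization.  Ties are
    broken toward smaller M, then smaller gamma.  ``valid_module_counts``
    tracks, per cell, how many modules have at least ``min_module_size``
    leaves — modules of one or two micro-regions carry no internal community
    structure and are reported as invalid.
    """
    gammas = [float(g) for g in gammas]
    if not gammas:
        raise ParameterError("empty gamma grid")
    n = pair.n_nodes
    if m_range is None:
        m_range = range(2, min(120, n) + 1)
    module_counts = sorted(int(m) for m in m_range)
    if not module_counts:
        raise ParameterError("empty module-count range")
    if module_counts[0] < 2 or module_counts[-1] > n:
        raise ParameterError(
            f"module counts must lie in [2, {n}], got "
            f"[{module_counts[0]}, {module_counts[-1]}]"
        )
    if min_module_size < 1:
        raise ParameterError("min_module_size must be >= 1")

    shape = (len(gammas), len(module_counts))
    q_f_grid = np.full(shape, np.nan)
    q_s_grid = np.full(shape, np.nan)
    t_grid = np.full(shape, np.nan)
    chi_grid = np.full(shape, np.nan)
    valid_grid = np.zeros(shape, dtype=int)
    partitions: dict[tuple[int, int], Partition] = {}
    trees: list[MergeTree] = []

    for gi, g in enumerate(gammas):
        fused = fuse(pair, g)
        tree = build_tree(fused, exclude_self=exclude_self)
        trees.append(tree)
        for mi, m in enumerate(module_counts):
            p = cut(tree, m)
            partitions[(gi, mi)] = p
            qf = modularity(pair.fc_bin, p)
            qs = modularity(pair.sc_bin, p)
            t = t_fs(pair, p, strategy=t_fs_strategy)
            q_f_grid[gi, mi] = qf
            q_s_grid[gi, mi] = qs
            t_grid[gi, mi] = t
            chi_grid[gi, mi] = chi(qf, qs, t)
            sizes = np.bincount(
                np.unique(p.labels, return_inverse=True)[1]
            )
            valid_grid[gi, mi] = int((sizes >= min_module_size).sum())

    if np.all(np.isnan(chi_grid)):
        raise GammaSFCError("chi undefined over the whole (gamma, M) grid")
    best = np.nanmax(chi_grid)
    cand = np.argwhere(chi_grid == best)
    # ties: smaller M first, then smaller gamma
    gi, mi = min(cand, key=lambda c: (module_counts[c[1]], gammas[c[0]]))
    optimum = (gammas[gi], module_counts[mi], float(best))
    return CrossModularityGrid(
        gammas=gammas,
        module_counts=module_counts,
        q_f=q_f_grid,
        q_s=q_s_grid,
        t_fs=t_grid,
        chi=chi_grid,
        valid_module_counts=valid_grid,
        min_module_size=min_module_size,
        optimum=optimum,
        optimum_partition=partitions[(gi, mi)],
        optimum_tree=trees[gi],
    )
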