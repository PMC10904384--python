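"""Node strength, macro-region aggregation, module segregation, correlations.

These metrics describe how graph weight redistributes as gamma moves between
structure and function: per-node strength (row sums of the fused matrix, with
a normalized variant for brain maps), its distribution across macro-regions,
and per-module segregation — the mean intra-module weight, a proxy for how
self-contained a module is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateGraphError,
    InsufficientDataError,
    ParameterError,
    ValidationError,
)
from .fusion import FusedMatrix
from .hierarchy import Partition, TreeMetricsTable
from .io import NodeLabeling

__all__ = [
    "StrengthTable",
    "SegregationTable",
    "node_strength",
    "group_by_labels",
    "module_segregation",
    "metric_correlations",
]


@dataclass
class StrengthTable:
    """Per-node strength of a fused matrix at one gamma."""

    gamma: float
    table: pd.DataFrame  # index: node id; columns: strength, normalized_strength


@dataclass
class SegregationTable:
    """Per-module mean intra-module weight (NaN for singleton modules)."""

    gamma: float
    table: pd.DataFrame  # index: module label; columns: segregation, ms


def node_strength(fused: FusedMatrix, normalization: str = "max") -> StrengthTable:
    """Row-sum strength per node, plus a normalized column.

    ``normalization='max'`` (default, the brain-map convention) divides by the
    maximum strength so the strongest node reads 1; ``'n-1'`` divides by the
    number of possible neighbors instead.
    """
    if normalization not in ("max", "n-1"):
        raise ParameterError(f"unknown normalization {normalization!r}")
    if fused.n_nodes < 2:
        raise ParameterError("need at least 2 nodes")
    strength = fused.values.sum(axis=1)
    smax = strength.max()
    if smax == 0:
        raise DegenerateGraphError("all-zero fused matrix has no strength")
    denom = smax if normalization == "max" else fused.n_nodes - 1
    table = pd.DataFrame(
        {"strength": strength, "normalized_strength": strength / denom},
        index=list(fused.node_ids),
    )
    return StrengthTable(gamma=fused.gamma, table=table)


def group_by_labels(
    table: StrengthTable, labeling: NodeLabeling
) -> dict[str, np.ndarray]:
    """Strength values grouped by node label (e.g. macro-region).

    Every node in the strength table must carry a label; group sizes sum to N.
    """
    missing = [n for n in table.table.index if n not in labeling._index]
    if missing:
        raise ValidationError(f"nodes without labels: {missing[:5]}")
    groups: dict[str, list[float]] = {}
    for node, s in table.table["strength"].items():
        groups.setdefault(labeling.label_of(node), []).append(float(s))
    return {lab: np.asarray(v) for lab, v in groups.items()}


def module_segregation(fused: FusedMatrix, p: Partition) -> SegregationTable:
    """Mean intra-module weight per module.

    For module m: sum of w_ij over ordered intra-module pairs i != j divided
    by |m| * (|m| - 1).  Singleton modules have no intra pairs and are
    reported as NaN rather than 0, so they never enter metric correlations.
    """
    try:
        labels = np.asarray([p.label_of(n) for n in fused.node_ids])
    except KeyError as exc:
        raise ValidationError(f"partition does not cover node {exc}") from exc
    rows = []
    for lab in dict.fromkeys(labels.tolist()):
        ix = np.where(labels == lab)[0]
        size = len(ix)
        if size < 2:
            seg = float("nan")
        else:
            sub = fused.values[np.ix_(ix, ix)]
            seg = float(sub.sum() / (size * (size - 1)))
        rows.append({"module": lab, "segregation": seg, "ms": size})
    table = pd.DataFrame(rows).set_index("module").sort_index()
    return SegregationTable(gamma=fused.gamma, table=table)


def metric_correlations(
    tree_metrics_table: TreeMetricsTable, segregation: SegregationTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r (and two-sided p) between module-level metrics.

    Joins MS, MSI, MH and segregation on module label, drops modules with any
    undefined value, and correlates every metric pair.  Returns (r, p) as two
    square DataFrames.
    """
    joined = tree_metrics_table.module_table.join(
        segregation.table[["segregation"]], how="inner"
    ).dropna()
    if len(joined) < 3:
        raise InsufficientDataError(
            f"only {len(joined)} modules with defined metrics (need >= 3)"
        )
    cols = ["ms", "msi", "mh", "segregation"]
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if i < j:
                res = stats.pearsonr(joined[a], joined[b])
                r.loc[a, b] = r.loc[b, a] = res.statistic
                p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p
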