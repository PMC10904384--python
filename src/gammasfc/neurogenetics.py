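"""Module-level transcriptomic scoring against brain-disorder gene sets.

Regional expression samples (e.g. Allen Human Brain Atlas samples already
mapped to micro-regions/modules upstream) are averaged within each module of
a partition.  For every disorder gene set the mean expression of its matched
genes is computed per module, then z-scored ACROSS modules; |z| > 2 flags a
module as unusually high or low in disorder-related expression.  Disorders
can additionally be pooled into disease groups (union of their gene sets)
and scored the same way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    GeneMatchError,
    InsufficientDataError,
    ParameterError,
    ValidationError,
)
from .io import GeneSetCollection, NodeLabeling

logger = logging.getLogger("gammasfc")

#: |z| beyond which a module is flagged high/low
Z_THRESHOLD = 2.0

__all__ = [
    "ModuleExpression",
    "DisorderScoreTable",
    "aggregate_samples",
    "disorder_scores",
    "group_scores",
    "Z_THRESHOLD",
]


@dataclass
class ModuleExpression:
    """Mean expression per (module, gene), with sample counts per module."""

    values: pd.DataFrame  # index: module label; columns: gene symbols
    n_samples_per_module: pd.Series

    def __post_init__(self) -> None:
        if self.values.isna().all(axis=1).any():
            raise ValidationError("a module row is entirely missing")
        cols = [str(c) for c in self.values.columns]
        if len(set(c.upper() for c in cols)) != len(cols):
            raise ValidationError("gene symbols are not unique (case-insensitive)")

    @property
    def modules(self) -> list:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return [str(c) for c in self.values.columns]


@dataclass
class DisorderScoreTable:
    """Long-format scores: one row per (module, set)."""

    table: pd.DataFrame  # columns: module, set, mean_expression, z, flag
    n_genes_matched: dict[str, int]
    level: str = "disorder"  # or "group"
    threshold: float = Z_THRESHOLD

    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["flag"] != "none"]


def aggregate_samples(
    sample_expression: pd.DataFrame, sample_modules: NodeLabeling
) -> ModuleExpression:
    """Average a samples x genes matrix within modules.

    Every sample (row) must be labeled with its module; samples the labeling
    does not mention are an error, while labeled modules that end up with no
    samples are dropped with a warning.
    """
    if sample_expression.empty:
        raise ValidationError("no expression samples")
    sample_ids = [str(s) for s in sample_expression.index]
    missing = [s for s in sample_ids if s not in sample_modules._index]
    if missing:
        raise ValidationError(f"unlabeled samples: {missing[:5]}")
    labels = [sample_modules.label_of(s) for s in sample_ids]
    grouped = sample_expression.groupby(pd.Index(labels, name="module"))
    values = grouped.mean()
    counts = grouped.size()
    declared = set(sample_modules.label_set())
    empty = declared - set(values.index)
    if empty:
        logger.warning("module(s) without samples dropped: %s", sorted(empty))
    return ModuleExpression(values=values, n_samples_per_module=counts)


def _match_genes(expr: ModuleExpression, symbols: list[str]) -> list[str]:
    """Case-insensitive exact matching of set symbols to expression columns."""
    by_upper = {g.upper(): g for g in expr.genes}
    matched, unmatched = [], []
    for s in symbols:
        hit = by_upper.get(str(s).upper())
        (matched if hit is not None else unmatched).append(hit or s)
    if unmatched:
        logger.warning("%d unmatched gene symbol(s): %s", len(unmatched), unmatched[:5])
    return [g for g in matched if g in set(expr.genes)]


def _score(
    expr: ModuleExpression,
    named_sets: dict[str, list[str]],
    level: str,
    center: str,
    threshold: float,
) -> DisorderScoreTable:
    if center not in ("mean", "median"):
        raise ParameterError(f"unknown center {center!r}")
    if len(expr.modules) < 2:
        raise InsufficientDataError("need >= 2 modules for across-module z-scores")
    rows = []
    n_matched: dict[str, int] = {}
    for name, symbols in named_sets.items():
        genes = _match_genes(expr, symbols)
        if not genes:
            raise GeneMatchError(
                f"{level} set {name!r} matched no gene in the expression matrix"
            )
        n_matched[name] = len(genes)
        sub = expr.values[genes]
        x = sub.mean(axis=1) if center == "mean" else sub.median(axis=1)
        sd = x.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            z = pd.Series(np.nan, index=x.index)
        else:
            z = (x - x.mean()) / sd
        for mod in expr.modules:
            zv = float(z.loc[mod])
            flag = "none"
            if np.isfinite(zv):
                if zv > threshold:
                    flag = "high"
                elif zv < -threshold:
                    flag = "low"
            rows.append(
                {
                    "module": mod,
                    "set": name,
                    "mean_expression": float(x.loc[mod]),
                    "z": zv,
                    "flag": flag,
                }
            )
    return DisorderScoreTable(
        table=pd.DataFrame(rows),
        n_genes_matched=n_matched,
        level=level,
        threshold=threshold,
    )


def disorder_scores(
    expr: ModuleExpression,
    sets: GeneSetCollection,
    center: str = "mean",
    threshold: float = Z_THRESHOLD,
) -> DisorderScoreTable:
    """Per-(module, disorder) mean expression, across-module z and flags.

    For each disorder, matched-gene expression is summarized per module
    (``center='mean'`` by default; ``'median'`` available), z-scored across
    modules with the sample standard deviation (n-1), and flagged ``high``
    (z > 2) or ``low`` (z < -2).  Zero across-module variance yields NaN z
    and no flags.  A disorder matching no gene raises
    :class:`GeneMatchError`.
    """
    return _score(expr, sets.sets, "disorder", center, threshold)


def group_scores(
    expr: ModuleExpression,
    sets: GeneSetCollection,
    center: str = "mean",
    threshold: float = Z_THRESHOLD,
) -> DisorderScoreTable:
    """Disease-group scores: pool the union of member-disorder gene symbols.

    A gene shared by two member disorders counts once in the pooled set.
    """
    groups = sets.groups()
    if not groups:
        raise ParameterError("gene-set collection has no group mapping")
    pooled: dict[str, list[str]] = {}
    for gname, members in groups.items():
        union: dict[str, None] = {}
        for d in members:
            for g in sets.sets[d]:
                union.setdefault(g, None)
        if not union:
            raise GeneMatchError(f"disease group {gname!r} pools no genes")
        pooled[gname] = list(union)
    return _score(expr, pooled, "group", center, threshold)
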