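"""Population aggregation, density matching and binarization of SC/FC pairs.

Subject-level matrices are reduced to a population matrix by taking, for each
link, the median across subjects (absent streamlines count as 0).  Structural
connectivity is naturally sparse while functional correlations are dense, so
the functional population matrix is thresholded to the structural link count
before both are binarized — the contract every downstream fusion step relies
on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DensityError, ParameterError, ValidationError
from .io import ConnectivityMatrix

logger = logging.getLogger("gammasfc")

__all__ = ["PopulationPair", "population_median", "match_density_and_binarize"]


@dataclass
class PopulationPair:
    """Density-matched, binarized population SC/FC pair.

    ``density`` is the fraction of possible (undirected, off-diagonal) links
    present in the binary structural matrix; ``tie_count`` records how many
    extra functional links were kept because they tied with the K-th ranked
    correlation.
    """

    sc_bin: ConnectivityMatrix
    fc_bin: ConnectivityMatrix
    sc_raw_population: ConnectivityMatrix
    fc_raw_population: ConnectivityMatrix
    density: float
    tie_count: int = 0

    def __post_init__(self) -> None:
        if self.sc_bin.node_ids != self.fc_bin.node_ids:
            raise ValidationError("sc_bin and fc_bin node ids differ")
        if not (self.sc_bin.is_binary() and self.fc_bin.is_binary()):
            raise ValidationError("population pair matrices must be binary")

    @property
    def node_ids(self) -> list[str]:
        return self.sc_bin.node_ids

    @property
    def n_nodes(self) -> int:
        return self.sc_bin.n_nodes


def population_median(
    subject_matrices: list[ConnectivityMatrix],
) -> ConnectivityMatrix:
    """Entry-wise median across subjects for every link.

    All subjects must share the same node order; the result inherits the
    modality of the inputs.  The median is over the full subject vector,
    including zeros (a subject without the link contributes 0).
    """
    if not subject_matrices:
        raise ParameterError("need at least one subject matrix")
    first = subject_matrices[0]
    for m in subject_matrices[1:]:
        if m.node_ids != first.node_ids:
            raise ValidationError("subject matrices have mismatched node ids")
        if m.modality != first.modality:
            raise ValidationError("subject matrices have mismatched modality")
    stack = np.stack([m.values for m in subject_matrices])
    med = np.median(stack, axis=0)
    return ConnectivityMatrix(
        node_ids=list(first.node_ids), values=med, modality=first.modality
    )


def match_density_and_binarize(
    sc_pop: ConnectivityMatrix,
    fc_pop: ConnectivityMatrix,
    fc_threshold: str = "positive",
) -> PopulationPair:
    """Threshold FC to SC's link count and binarize both matrices.

    The structural matrix binarizes as ``sc > 0``.  The functional matrix
    keeps its K strongest links, K being the structural link count, ranked by
    signed value (``fc_threshold='positive'``, default) or by magnitude
    (``'absolute'``).  Links tied exactly with the K-th value are all kept,
    so the functional density can exceed the structural one by the tie-group
    size; the tie count is logged and recorded.
    """
    if fc_threshold not in ("positive", "absolute"):
        raise ParameterError(f"unknown fc_threshold {fc_threshold!r}")
    if sc_pop.node_ids != fc_pop.node_ids:
        raise ValidationError("SC and FC population matrices share no node order")
    n = sc_pop.n_nodes
    iu = np.triu_indices(n, k=1)

    sc_links = sc_pop.values[iu] > 0
    k = int(sc_links.sum())
    if k == 0:
        raise DensityError("structural population matrix has no links", 0.0)

    fc_vals = fc_pop.values[iu]
    score = fc_vals if fc_threshold == "positive" else np.abs(fc_vals)
    if fc_threshold == "positive":
        eligible = fc_vals > 0
    else:
        eligible = fc_vals != 0
    n_eligible = int(eligible.sum())
    n_pairs = len(fc_vals)
    if n_eligible < k:
        raise DensityError(
            f"only {n_eligible} eligible FC links for target K={k}",
            achievable_density=n_eligible / n_pairs,
        )
    kth = np.sort(score[eligible])[::-1][k - 1]
    fc_links = eligible & (score >= kth)
    tie_count = int(fc_links.sum()) - k
    if tie_count:
        logger.info(
            "FC thresholding kept %d tied link(s) beyond K=%d", tie_count, k
        )

    def _binary(links: np.ndarray) -> np.ndarray:
        out = np.zeros((n, n))
        out[iu] = links.astype(float)
        return out + out.T

    sc_bin = ConnectivityMatrix(
        node_ids=list(sc_pop.node_ids),
        values=_binary(sc_links),
        modality="structural",
        weighted=False,
    )
    fc_bin = ConnectivityMatrix(
        node_ids=list(fc_pop.node_ids),
        values=_binary(fc_links),
        modality="functional",
        weighted=False,
    )
    return PopulationPair(
        sc_bin=sc_bin,
        fc_bin=fc_bin,
        sc_raw_population=sc_pop,
        fc_raw_population=fc_pop,
        density=k / n_pairs,
        tie_count=tie_count,
    )
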