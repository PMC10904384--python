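"""Annotate partition modules against reference atlas labelings.

A data-driven partition gains meaning when its modules are mapped onto known
reference systems — anatomical parcels (e.g. Desikan-Killiany regions) or
functional systems (resting-state networks).  The overlap matrix tabulates,
for every (module, atlas label) pair, either the fraction of the module
falling inside the label or their DICE coefficient; ``top_labels`` then ranks
the best-matching labels per module.

Overlap is computed at the granularity of the shared elements (micro-regions
by default); optional per-element weights (e.g. voxel counts per
micro-region) recover voxel-level proportions without handling voxel data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .hierarchy import Partition
from .io import NodeLabeling

__all__ = ["overlap_matrix", "top_labels"]


def overlap_matrix(
    p: Partition,
    atlas: NodeLabeling,
    mode: str = "fraction",
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Modules x atlas-labels overlap table.

    ``mode='fraction'``: entry (m, l) = |m & l| / |m| — rows sum to 1 when
    the atlas covers every element.  ``mode='dice'``: 2|m & l| / (|m| + |l|).
    Sizes are weighted sums when ``weights`` is given (default weight 1).
    """
    if mode not in ("fraction", "dice"):
        raise ParameterError(f"unknown overlap mode {mode!r}")
    if set(p.node_ids) != set(atlas.node_ids):
        raise ValidationError("partition and atlas cover different elements")
    w = {n: 1.0 for n in p.node_ids}
    if weights is not None:
        missing = [n for n in p.node_ids if n not in weights]
        if missing:
            raise ValidationError(f"elements without weights: {missing[:5]}")
        w = {n: float(weights[n]) for n in p.node_ids}

    module_labels = list(dict.fromkeys(p.labels))
    atlas_labels = atlas.label_set()
    inter = pd.DataFrame(0.0, index=module_labels, columns=atlas_labels)
    module_size = {m: 0.0 for m in module_labels}
    atlas_size = {l: 0.0 for l in atlas_labels}
    for node, mod in zip(p.node_ids, p.labels):
        lab = atlas.label_of(node)
        inter.loc[mod, lab] += w[node]
        module_size[mod] += w[node]
        atlas_size[lab] += w[node]

    if mode == "fraction":
        out = inter.div(pd.Series(module_size), axis=0)
    else:
        denom = np.add.outer(
            np.array([module_size[m] for m in module_labels]),
            np.array([atlas_size[l] for l in atlas_labels]),
        )
        out = 2.0 * inter / denom
    out.index.name = "module"
    out.columns.name = "atlas_label"
    return out


def top_labels(overlaps: pd.DataFrame, k: int = 3) -> dict:
    """Per module, the k atlas labels with highest overlap.

    Returned descending by overlap; exact ties are ordered by label name.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    out = {}
    for mod, row in overlaps.iterrows():
        ranked = sorted(row.items(), key=lambda kv: (-kv[1], str(kv[0])))
        out[mod] = [lab for lab, _ in ranked[:k]]
    return out
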