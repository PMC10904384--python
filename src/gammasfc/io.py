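"""On-disk formats: connectivity matrices, partitions, labelings, gene sets, trees.

Canonical formats are plain text so that fixtures and deposited derivatives
both load: TSV matrices with node ids in the header row and first column,
two-column TSV partitions/labelings, GMT gene sets, and merge-table TSV or
Newick for dendrograms.  Large matrices may instead be stored as ``.npz``
with a JSON sidecar (same stem, ``.json`` suffix) carrying the node list.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .hierarchy import MergeTree, Partition

logger = logging.getLogger("gammasfc")

SYMMETRY_TOL = 1e-8
MODALITIES = ("structural", "functional", "fused")

__all__ = [
    "ConnectivityMatrix",
    "NodeLabeling",
    "GeneSetCollection",
    "read_matrix",
    "write_matrix",
    "read_partition",
    "write_partition",
    "read_labeling",
    "write_labeling",
    "read_gene_sets",
    "write_gene_sets",
    "read_tree",
    "write_tree",
    "to_newick",
    "write_newick",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityMatrix:
    """Square symmetric connectivity over an ordered node list.

    ``modality`` tags the physical meaning of the weights: ``structural``
    (nonnegative streamline counts), ``functional`` (Pearson correlations in
    [-1, 1]) or ``fused`` (gamma-weighted combination).  Asymmetries up to
    1e-8 are averaged away; anything larger is an error, since it usually
    signals misaligned node orders rather than rounding.  The diagonal is
    forced to zero: self-connections are undefined for both modalities.
    """

    node_ids: list[str]
    values: np.ndarray
    modality: str
    weighted: bool = True

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        self.node_ids = [str(n) for n in self.node_ids]
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValidationError("duplicate node ids")
        v = np.asarray(self.values, dtype=float)
        n = len(self.node_ids)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"matrix is not square: shape {v.shape}")
        if v.shape[0] != n:
            raise ValidationError(
                f"matrix dimension {v.shape[0]} != {n} node ids"
            )
        asym = np.abs(v - v.T).max() if n else 0.0
        if asym > SYMMETRY_TOL:
            raise ValidationError(
                f"matrix asymmetry {asym:.3g} exceeds tolerance {SYMMETRY_TOL}"
            )
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        if self.modality == "structural" and v.min() < 0:
            raise ValidationError("structural matrix has negative entries")
        if self.modality == "functional" and (v.min() < -1 or v.max() > 1):
            raise ValidationError("functional values outside [-1, 1]")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def is_binary(self) -> bool:
        return bool(np.isin(self.values, (0.0, 1.0)).all())


@dataclass
class NodeLabeling:
    """One categorical label per node (macro-region, atlas region, module)."""

    node_ids: list[str]
    labels: list
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.node_ids = [str(n) for n in self.node_ids]
        if len(self.node_ids) != len(self.labels):
            raise ValidationError("node_ids and labels differ in length")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValidationError("duplicate node ids in labeling")
        if not self.labels:
            raise ValidationError("empty labeling")
        self._index = dict(zip(self.node_ids, self.labels))

    def label_of(self, node_id: str):
        return self._index[str(node_id)]

    def label_set(self) -> list:
        seen: dict = {}
        for l in self.labels:
            seen.setdefault(l, None)
        return list(seen)


@dataclass
class GeneSetCollection:
    """Named gene sets (disorders), optionally grouped into disease groups."""

    sets: dict[str, list[str]]
    group: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} has duplicate symbols")

    def groups(self) -> dict[str, list[str]]:
        """Mapping group name -> member set names (insertion order)."""
        if not self.group:
            return {}
        out: dict[str, list[str]] = {}
        for name in self.sets:
            g = self.group.get(name)
            if g is not None:
                out.setdefault(g, []).append(name)
        return out


# ---------------------------------------------------------------------------
# connectivity matrices
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, modality: str) -> ConnectivityMatrix:
    """Load a connectivity matrix from TSV or ``.npz`` + JSON sidecar.

    The TSV dialect has node ids in the header row and first column; row and
    column orders must agree.  Validation (squareness, symmetry to 1e-8,
    modality value range) happens on construction; the diagonal is zeroed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npz":
        with np.load(path) as npz:
            values = np.asarray(npz["values"], dtype=float)
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FormatError(f"missing node-list sidecar {sidecar}")
        node_ids = [str(n) for n in json.loads(sidecar.read_text())["node_ids"]]
    else:
        try:
            frame = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # malformed TSV
            raise FormatError(f"cannot parse {path} as TSV matrix: {exc}") from exc
        if frame.shape[0] != frame.shape[1]:
            raise FormatError(
                f"{path}: matrix is not square ({frame.shape[0]}x{frame.shape[1]})"
            )
        row_ids = [str(i) for i in frame.index]
        col_ids = [str(c) for c in frame.columns]
        if row_ids != col_ids:
            raise ValidationError(f"{path}: row ids differ from column ids")
        node_ids = row_ids
        values = frame.to_numpy(dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise FormatError(f"{path}: array is not square {values.shape}")
    return ConnectivityMatrix(node_ids=node_ids, values=values, modality=modality)


def write_matrix(mat: ConnectivityMatrix, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".npz":
        np.savez_compressed(path, values=mat.values)
        path.with_suffix(".json").write_text(
            json.dumps({"node_ids": mat.node_ids})
        )
    else:
        pd.DataFrame(mat.values, index=mat.node_ids, columns=mat.node_ids).to_csv(
            path, sep="\t", float_format="%.17g"
        )


# ---------------------------------------------------------------------------
# partitions and labelings (two-column TSV)
# ---------------------------------------------------------------------------

def _read_two_column(path: Path, what: str) -> tuple[list[str], list]:
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty {what} file") from exc
    if frame.shape[1] != 2 or frame.empty:
        raise FormatError(f"{path}: expected two non-empty columns")
    ids = frame.iloc[:, 0].tolist()
    raw = frame.iloc[:, 1].tolist()
    try:
        labels = [int(l) for l in raw]
    except ValueError:
        labels = raw
    return ids, labels


def write_partition(p: Partition, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"node_id": p.node_ids, "module_label": p.labels}).to_csv(
        path, sep="\t", index=False
    )


def read_partition(path: str | Path, node_ids: list[str] | None = None) -> Partition:
    """Read a two-column (node_id, module_label) TSV.

    If ``node_ids`` is given, any node in the file outside that universe is a
    :class:`ValidationError`.
    """
    ids, labels = _read_two_column(Path(path), "partition")
    if node_ids is not None:
        known = set(str(n) for n in node_ids)
        unknown = [n for n in ids if n not in known]
        if unknown:
            raise ValidationError(f"unknown node(s) in partition: {unknown[:5]}")
    return Partition(node_ids=ids, labels=labels)


def write_labeling(labeling: NodeLabeling, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"node_id": labeling.node_ids, "label": labeling.labels}).to_csv(
        path, sep="\t", index=False
    )


def read_labeling(path: str | Path) -> NodeLabeling:
    ids, labels = _read_two_column(Path(path), "labeling")
    return NodeLabeling(node_ids=ids, labels=labels)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(
    path: str | Path, description_as_group: bool = False
) -> GeneSetCollection:
    """Parse a GMT file: ``name TAB description TAB gene1 TAB gene2 ...``.

    Duplicate symbols within one line are dropped with a warning; an empty
    gene list or a repeated set name is a :class:`FormatError`.  With
    ``description_as_group=True`` the description column is interpreted as
    the disease-group name of the set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: dict[str, list[str]] = {}
    group: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line has {len(fields)} fields "
                "(need name, description, >=1 gene)"
            )
        name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        if not genes:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        deduped = list(dict.fromkeys(genes))
        if len(deduped) != len(genes):
            logger.warning(
                "gene set %r: %d duplicate symbol(s) dropped",
                name,
                len(genes) - len(deduped),
            )
        sets[name] = deduped
        if description_as_group:
            group[name] = desc
    return GeneSetCollection(sets=sets, group=group if description_as_group else None)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for name, genes in collection.sets.items():
        desc = (collection.group or {}).get(name, "na")
        lines.append("\t".join([name, desc, *genes]))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# merge trees
# ---------------------------------------------------------------------------

def write_tree(tree: MergeTree, path: str | Path) -> None:
    """Serialize a dendrogram as leaf list + 4-column merge table TSV.

    Leaves appear first as ``#leaf<TAB>id`` comment lines (defining leaf
    index order), followed by one row per merge: left_id, right_id, distance,
    new_cluster_size, in scipy cluster-id convention.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"#leaf\t{leaf}" for leaf in tree.leaf_ids]
    lines.append("left_id\tright_id\tdistance\tnew_cluster_size")
    for a, b, d, s in tree.merges:
        lines.append(f"{int(a)}\t{int(b)}\t{d:.17g}\t{int(s)}")
    path.write_text("\n".join(lines) + "\n")


def read_tree(path: str | Path) -> MergeTree:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    leaf_ids: list[str] = []
    rows: list[list[float]] = []
    header_seen = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("#leaf\t"):
            leaf_ids.append(line.split("\t", 1)[1])
        elif line.startswith("left_id"):
            header_seen = True
        elif line.strip():
            if not header_seen:
                raise FormatError(f"{path}:{lineno}: merge row before header")
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            rows.append([float(x) for x in parts])
    if not leaf_ids or not rows:
        raise FormatError(f"{path}: no leaves or no merges found")
    return MergeTree(leaf_ids=leaf_ids, merges=np.asarray(rows))


def to_newick(tree: MergeTree) -> str:
    """Render the dendrogram as a Newick string.

    Branch lengths are merge-height differences (parent height minus child
    height; leaves sit at height 0), so root-to-leaf path lengths reproduce
    the merge distances of an ultrametric tree.
    """
    n = tree.n_leaves

    def height(c: int) -> float:
        return 0.0 if c < n else float(tree.merges[c - n, 2])

    def render(c: int, parent_h: float) -> str:
        bl = parent_h - height(c)
        if c < n:
            name = str(tree.leaf_ids[c]).replace(" ", "_")
            return f"{name}:{bl:.17g}"
        a, b = int(tree.merges[c - n, 0]), int(tree.merges[c - n, 1])
        h = height(c)
        return f"({render(a, h)},{render(b, h)}):{bl:.17g}"

    import sys

    root = 2 * n - 2
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * n + 100))
    try:
        h = height(root)
        a, b = int(tree.merges[-1, 0]), int(tree.merges[-1, 1])
        return f"({render(a, h)},{render(b, h)});"
    finally:
        sys.setrecursionlimit(old)


def write_newick(tree: MergeTree, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(to_newick(tree) + "\n")
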