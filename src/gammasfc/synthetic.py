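"""Synthetic paired SC/FC cohorts and expression data with planted structure.

The generator emulates the statistical skeleton the pipeline assumes: a
common modular organization expressed in two modalities with
modality-specific noise.  Structural subjects are planted-partition Bernoulli
graphs (intra-module link probability ``p_in`` > inter-module ``p_out``) with
per-subject link flips; functional subjects are block-correlation matrices
(``fc_block_mu_in`` intra, ``fc_block_mu_out`` inter) plus Gaussian noise,
clipped to [-1, 1].  Expression data are standard-normal baselines with
planted (module, gene-set, effect-size) shifts, so disorder-flag calibration
can be checked under the null and under known effects.

Defaults encode the reference desk-scale study: 60 nodes in 4 equal modules,
20 subjects, p_in = 0.8, p_out = 0.05, mu_in = 0.6, mu_out = 0.05, FC noise
sd 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .hierarchy import Partition
from .io import ConnectivityMatrix, GeneSetCollection, NodeLabeling
from .population import PopulationPair, match_density_and_binarize, population_median

__all__ = [
    "SyntheticSpec",
    "generate_cohort",
    "generate_expression",
    "cohort_population_pair",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study; ``seed`` is mandatory."""

    seed: int
    n_nodes: int = 60
    module_sizes: tuple[int, ...] = (15, 15, 15, 15)
    sub_module_sizes: tuple[int, ...] | None = None  # optional nested level
    p_in: float = 0.8
    p_out: float = 0.05
    p_in_sub: float | None = None  # boosted link prob inside sub-modules
    fc_block_mu_in: float = 0.6
    fc_block_mu_out: float = 0.05
    fc_block_mu_in_sub: float | None = None
    fc_noise_sd: float = 0.1
    n_subjects: int = 20
    subject_flip_prob: float = 0.05
    subject_noise_sd: float = 0.1
    # expression generation
    n_genes: int = 200
    genes_per_set: int = 10
    samples_per_module: int = 4
    planted: tuple[tuple[int, str, float], ...] = ()  # (module, set name, effect)
    n_null_sets: int = 0
    n_groups: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ParameterError("seed is mandatory")
        if sum(self.module_sizes) != self.n_nodes:
            raise ParameterError(
                f"module sizes sum to {sum(self.module_sizes)}, not {self.n_nodes}"
            )
        if self.sub_module_sizes is not None and sum(self.sub_module_sizes) != self.n_nodes:
            raise ParameterError("sub-module sizes do not sum to n_nodes")
        for name in ("p_in", "p_out", "subject_flip_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.samples_per_module < 2:
            raise ParameterError("need >= 2 expression samples per module")
        if self.n_subjects < 1:
            raise ParameterError("need >= 1 subject")

    def node_ids(self) -> list[str]:
        width = len(str(self.n_nodes))
        return [f"n{i:0{width}d}" for i in range(1, self.n_nodes + 1)]

    def ground_truth(self) -> Partition:
        labels: list[int] = []
        for mod, size in enumerate(self.module_sizes, start=1):
            labels.extend([mod] * size)
        return Partition(node_ids=self.node_ids(), labels=labels)

    def _block_labels(self, sizes: tuple[int, ...]) -> np.ndarray:
        out = np.empty(self.n_nodes, dtype=int)
        start = 0
        for b, size in enumerate(sizes):
            out[start : start + size] = b
            start += size
        return out


def _symmetric_from_upper(n: int, upper: np.ndarray) -> np.ndarray:
    out = np.zeros((n, n))
    out[np.triu_indices(n, k=1)] = upper
    return out + out.T


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[list[tuple[ConnectivityMatrix, ConnectivityMatrix]], Partition]:
    """Draw the subject SC/FC pairs and return them with the ground truth.

    The structural backbone is drawn once (Bernoulli planted-partition graph);
    each subject then flips every potential link independently with
    ``subject_flip_prob``.  Functional subjects add iid Gaussian noise to the
    shared block-correlation template.  Bit-reproducible given ``seed``.
    """
    rng = np.random.default_rng([int(spec.seed), 0])
    n = spec.n_nodes
    ids = spec.node_ids()
    truth = spec.ground_truth()
    labels = spec._block_labels(spec.module_sizes)
    iu = np.triu_indices(n, k=1)
    same = labels[iu[0]] == labels[iu[1]]

    p_link = np.where(same, spec.p_in, spec.p_out)
    mu = np.where(same, spec.fc_block_mu_in, spec.fc_block_mu_out)
    if spec.sub_module_sizes is not None:
        sub = spec._block_labels(spec.sub_module_sizes)
        same_sub = sub[iu[0]] == sub[iu[1]]
        if spec.p_in_sub is not None:
            p_link = np.where(same_sub, spec.p_in_sub, p_link)
        if spec.fc_block_mu_in_sub is not None:
            mu = np.where(same_sub, spec.fc_block_mu_in_sub, mu)

    base_links = rng.random(len(p_link)) < p_link
    cohort = []
    for _ in range(spec.n_subjects):
        flips = rng.random(len(p_link)) < spec.subject_flip_prob
        links = np.where(flips, ~base_links, base_links)
        sc = ConnectivityMatrix(
            node_ids=list(ids),
            values=_symmetric_from_upper(n, links.astype(float)),
            modality="structural",
            weighted=False,
        )
        noisy = np.clip(
            mu + rng.normal(0.0, spec.subject_noise_sd, size=len(mu)), -1.0, 1.0
        )
        fc = ConnectivityMatrix(
            node_ids=list(ids),
            values=_symmetric_from_upper(n, noisy),
            modality="functional",
        )
        cohort.append((sc, fc))
    return cohort, truth


def cohort_population_pair(
    cohort: list[tuple[ConnectivityMatrix, ConnectivityMatrix]],
    fc_threshold: str = "positive",
) -> PopulationPair:
    """Population medians of a cohort, density-matched and binarized."""
    sc_pop = population_median([sc for sc, _ in cohort])
    fc_pop = population_median([fc for _, fc in cohort])
    return match_density_and_binarize(sc_pop, fc_pop, fc_threshold=fc_threshold)


def generate_expression(
    spec: SyntheticSpec, p: Partition
) -> tuple[pd.DataFrame, NodeLabeling, GeneSetCollection]:
    """Samples x genes expression with planted module-specific gene sets.

    Baseline expression is iid Normal(0, 1); each planted (module, set,
    effect) triple shifts the set's genes by ``effect`` (in noise-sd units)
    in that module's samples.  Gene sets are disjoint blocks of
    ``genes_per_set`` symbols; ``n_null_sets`` extra sets carry no shift.
    Returns the expression matrix, the sample->module labeling, and the GMT
    collection of the generated sets (grouped round-robin into ``n_groups``
    disease groups when requested).
    """
    rng = np.random.default_rng([int(spec.seed), 1])
    modules = list(dict.fromkeys(p.labels))
    for mod, _, _ in spec.planted:
        if mod not in modules:
            raise ParameterError(f"planted module {mod!r} not in partition")

    n_sets = len(spec.planted) + spec.n_null_sets
    if n_sets * spec.genes_per_set > spec.n_genes:
        raise ParameterError(
            f"{n_sets} sets x {spec.genes_per_set} genes exceed n_genes={spec.n_genes}"
        )
    genes = [f"GENE{i:04d}" for i in range(1, spec.n_genes + 1)]
    sample_ids, sample_labels = [], []
    for mod in modules:
        for s in range(1, spec.samples_per_module + 1):
            sample_ids.append(f"sample_m{mod}_{s}")
            sample_labels.append(mod)
    values = rng.normal(0.0, 1.0, size=(len(sample_ids), spec.n_genes))
    expr = pd.DataFrame(values, index=sample_ids, columns=genes)
    labeling = NodeLabeling(node_ids=sample_ids, labels=sample_labels)

    sets: dict[str, list[str]] = {}
    cursor = 0
    for mod, name, effect in spec.planted:
        block = genes[cursor : cursor + spec.genes_per_set]
        cursor += spec.genes_per_set
        sets[name] = block
        rows = [i for i, lab in enumerate(sample_labels) if lab == mod]
        expr.loc[expr.index[rows], block] += float(effect)
    for k in range(1, spec.n_null_sets + 1):
        block = genes[cursor : cursor + spec.genes_per_set]
        cursor += spec.genes_per_set
        sets[f"NULL{k:02d}"] = block

    group = None
    if spec.n_groups:
        names = list(sets)
        group = {
            name: f"G{(i % spec.n_groups) + 1}" for i, name in enumerate(names)
        }
    collection = GeneSetCollection(sets=sets, group=group)
    return expr, labeling, collection
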