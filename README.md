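# gammasfc

Multi-scale structure–function brain connectomics: fuse population
structural (SC) and functional (FC) connectivity with a single parameter γ,
build hierarchical module trees of the fused network, find the partition
that maximizes **cross-modularity** over (γ, M), and characterize the
resulting modules — network metrics, reference-atlas overlap, and
transcriptomic scoring against brain-disorder gene sets.

## Who this is for

Network neuroscientists who already have region-by-region connectivity
matrices (streamline counts from tractography, Pearson correlations from
rs-fMRI) and want a reproducible, file-based pipeline from subject matrices
to an annotated optimal brain partition — without touching raw MRI data.

## The method

Subject matrices are reduced to population matrices by the link-wise median.
FC is thresholded to SC's link count (keeping the strongest positive
correlations), both are binarized, and fused:

    γSFC = γ·FC_p + (1 − γ)·SC_p,   γ ∈ [0, 1]

so γ = 0 is pure structure, γ = 1 pure function, and every link weight is
one of {0, γ, 1−γ, 1}. For each γ, hierarchical agglomerative clustering
(WPGMA linkage on the correlation distance between connectivity rows) builds
a dendrogram; cutting it at M modules gives a partition at that scale. The
partition quality is the cross-modularity

    χ = (Q_F · Q_S · T_FS)^(1/3)

with Q_F, Q_S the Newman–Girvan modularities of the binary FC and SC
matrices under the *same* fused-tree partition, and T_FS the mean DICE
similarity between intra-module link sets of the two modalities. The
optimum (γ\*, M\*) maximizes χ over the grid. Tree metrics (module size MS,
multi-scale index MSI, height H, module height MH), module segregation,
atlas overlap, and per-module disorder gene-set z-scores (|z| > 2 flags)
describe the chosen partition.

## Worked example

Generate a synthetic cohort with four planted modules, build the population
pair, and search the (γ, M) grid:

```python
import gammasfc as g

spec = g.SyntheticSpec(seed=1)           # 60 nodes, 4 modules, 20 subjects
cohort, truth = g.generate_cohort(spec)
pair = g.cohort_population_pair(cohort)
print(round(pair.density, 4))            # 0.2299  (binary link density)

grid = g.optimize(pair, m_range=range(2, 13))
print(grid.optimum)                      # (0.0, 4, 0.7325559633441563)
print(grid.n_valid_modules_at_optimum)   # 4
```

The search recovers the planted scale M\* = 4 with χ\* ≈ 0.733; here SC and
FC encode the same four modules, so χ is flat in γ and the tie resolves to
the smallest γ. The recovered partition matches the planted one exactly
(adjusted Rand index 1.0). The same pipeline is available from the shell:

```bash
gammasfc synth --seed 1 --out data/
gammasfc build-population --sc-dir data/sc --fc-dir data/fc --out pop/
gammasfc optimize --pair pop/ --m-max 12 --out grid.tsv
# optimum: gamma*=0.0 M*=4 chi*=0.7326 (4 modules with >= 3 nodes)
```

or end-to-end via `gammasfc run --config config.json`.

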