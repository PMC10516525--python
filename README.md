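# cicada

Identification and analysis of **biologically meaningful heterotypic
doublets** in scRNA-seq data, with optional CITE-seq gating and spatial
(Visium) validation of cell-type co-localization.

Doublets — two cells captured under one barcode — are normally discarded as
artifacts. But when a tissue is only partially dissociated, some doublets
are physically interacting cell pairs (juxtacrine conjugates), and their
merged transcriptome carries information about the interaction. This
package separates those **biological doublets** from dissociation artifacts
and characterizes what distinguishes them.

## Who this is for

Computational biologists analyzing tumor-microenvironment (or other
immune-rich) scRNA-seq data who want to ask: *which cell types were
physically interacting, and what transcriptional program does the
interaction induce?*

## The method

1. **Multi-label cell-type scoring.** Every cell is scored in [0, 1] for
   each cell type using weighted marker gene sets (weights = one-vs-all
   log2 fold-changes from a labeled reference, cutoff log2FC > 5; > 3 for
   sparser spatial data). The score is a variance-adjusted squared distance

   d<sub>i</sub> = Σ<sub>g∈S</sub> w̃<sub>g</sub> · x<sub>ig</sub>² / v<sub>g</sub>

   mapped through the CDF of a gamma distribution fitted (method of
   moments) to a gene-wise permutation null. With CITE-seq data, scores
   are gated: a k=2 k-means split of each surface marker's CLR-normalized
   counts zeroes the scores of marker-negative cells.
2. **Calling.** Cells with exactly two cell-type scores > 0.75 are
   heterotypic doublet candidates; more than two, multiplets (excluded);
   cells with one score > 0.75 and all others ≤ 0.5 are high-confidence
   singletons.
3. **Synthetic-doublet null.** Singleton pairs of the two focal types are
   randomly combined by summing raw counts — a non-interacting doublet
   with the same cell-type composition. Unique mode yields
   min(|A|, |B|) doublets; resampled mode draws any number with
   replacement.
4. **Separation.** Candidate and synthetic doublets are merged (cells with
   ≥ 100 genes, genes present in ≥ 50% of each object's cells, mito/ribo
   genes removed), log-normalized, z-scaled, embedded with 30 PCs and
   clustered on a shared-nearest-neighbor graph (k = 20, Jaccard weights,
   modularity communities at resolution 0.25). Candidates in clusters
   containing **zero** synthetic doublets are biological; the rest are
   artifactual. Wilcoxon rank-sum DE (BH-adjusted) then contrasts
   biological vs synthetic doublets.
5. **Spatial validation.** On a Visium slide, a spot "co-localizes" two
   types when each contributes ≥ 10% of the spot's summed cell-type
   scores. The co-localization rate is tested against 1000 permutations
   of the score columns, and Moran's I (hex-lattice neighbors, Monte-Carlo
   p) measures spatial aggregation of the co-localized spots.

## Worked example

Everything below runs on simulated data with planted truth (no downloads):

```python
import cicada
from cicada.io_formats import lognormalize
from cicada.simulate import SimulationConfig, simulate_singlecell, reference_from_simulation

cfg = SimulationConfig(seed=1, n_bio_doublets=200, n_art_doublets=200)
expr, cite, truth = simulate_singlecell(cfg)           # 1000 genes, 1000 cells
sets = cicada.build_gene_sets(reference_from_simulation(cfg), 3.0)

scores = cicada.vam_score(lognormalize(expr.counts), expr.gene_ids,
                          expr.cell_ids, sets, seed=1)
calls = cicada.call_cells(scores)                      # 0.75 / 0.5 rules
pair = cicada.select_pair(calls)                       # -> ('typeA', 'typeB')

sds = cicada.make_synthetic_doublets(
    expr, calls.singletons_of(pair[0]), calls.singletons_of(pair[1]),
    mode="unique", seed=1)
het = expr.subset(cell_mask=[list(expr.cell_ids).index(c)
                             for c in calls.het_doublets_of(*pair)])
merged, origin = cicada.merge_and_filter(het, sds)
result = cicada.cluster_doublets(merged, origin)
print(result.table["classification"].value_counts())
```

```
classification
artifactual    200
synthetic      200
biological     190
Name: count, dtype: int64
```

The 190 biological calls are candidate doublets whose expression the
synthetic (non-interacting) null cannot reproduce — here, the cells
carrying the planted 4× interaction signature. Differential expression
against the synthetic doublets then recovers the planted interaction genes
at BH-adjusted p < 0.05:

```python
de = cicada.differential_expression(merged, result.biological_ids(),
                                    merged.cell_ids[origin == "synthetic"])
print(de.significant().head(3)[["gene", "log2FC", "adjusted_p"]])
```

```
        gene    log2FC    adjusted_p
0  gene_0068  1.513765  3.341067e-48
1  gene_0062  1.606065  4.940175e-48
2  gene_0070  1.579292  5.176962e-47
```

A command-line interface chains the same steps from a YAML config
(`cicada simulate|score|call|synth|separate|spatial|run-all --config cfg.yaml`).

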