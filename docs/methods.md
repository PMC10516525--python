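# Methods

This note documents the models, numerical choices and simulation design
behind the package, and what the test suite does and does not demonstrate.

## Pipeline model

The package assumes raw UMI counts from droplet scRNA-seq in which some
barcodes captured two physically associated cells. Its core claim is
operational: a doublet whose transcriptome cannot be reproduced by summing
two independent singletons of the same two cell types carries evidence of a
cell–cell interaction. All stages serve that comparison.

### Cell-type scoring

Cells are scored per cell type with weighted gene sets. For set S with
weights w (log2 fold-changes from a one-vs-all reference comparison,
rescaled so Σw̃ = |S| to keep distances comparable across sets of different
sizes), the squared variance-adjusted distance of cell i from the origin is

    d_i = Σ_{g∈S} w̃_g · x_ig² / v_g

on log-normalized (ln(1 + CP10K), not z-scaled) expression x, with v_g the
per-gene variance across cells floored at ε = 1e−8. The null distribution
of d is produced by permuting each gene's values independently across cells
(one full permuted matrix by default; configurable), visiting genes in
sorted-ID order on sorted values so the result is invariant to input
ordering. A gamma distribution is fitted to the pooled nonzero null
distances by method of moments and scores are its CDF evaluated at d,
giving values in [0, 1] that are near 0 for cells not expressing the set
and near 1 for cells far outside the null. Degenerate cases: a set whose
genes are entirely unexpressed scores 0 everywhere; a null with no spread
(e.g. identical cells) degrades to the indicator d > 0.

### CITE-seq gating

Antibody counts are CLR-transformed per cell across markers
(ln(1+x) minus the per-cell mean of ln(1+x); with a single-marker panel the
centering is skipped since it would annihilate the signal). Each marker's
values are split by 1-D k-means (k = 2, n_init = 10, fixed seed); cells in
the lower-centroid cluster are marker-negative. A cell keeps its score for
type T iff at least one of T's markers calls it positive ("any" logic, e.g.
T cells: CD4+ OR CD8+); a per-marker `invert` flag supports negative
gates (CD45− endothelial cells). Markers with constant counts skip gating
with a warning. Gating only ever zeroes scores, never raises them.

### Calling rules

With thresholds τ_hi = 0.75 and τ_lo = 0.5 (both configurable): exactly two
scores > τ_hi → heterotypic doublet (unordered pair label); more than two →
multiplet, recorded but excluded downstream; exactly one score > τ_hi with
all others ≤ τ_lo → high-confidence singleton; anything else unassigned.
Homotypic doublets are inherently invisible to this rule — the method
targets heterotypic interactions only.

### Synthetic doublets

The non-interacting null: elementwise sums of raw counts of two singletons
of the focal types. *Unique* mode shuffles both singleton lists (seeded)
and pairs the first min(|A|, |B|) — no cell is reused, so the yield is
capped by the smaller population (279 A + 685 B singletons give exactly 279
synthetic doublets). *Resampled* mode draws any number of pairs uniformly
with replacement, trading independence for yield; reused parents make
resampled synthetic doublets correlated, which slightly blurs the
separation stage (see Limitations).

### Separation

Candidate and synthetic doublets are filtered per object (cells ≥ 100
genes; genes present — nonzero — in ≥ 50% of that object's cells), merged
on the gene intersection, and mitochondrial (`^MT-`, case-insensitive) and
ribosomal (`^RP[SL]`) genes are removed. The merged matrix is
log-normalized, z-scaled per gene, reduced to 30 PCs (fewer, with a
warning, when cells are scarce), and clustered: k = 20 nearest neighbors in
PC space, shared-nearest-neighbor graph connecting every pair of cells with
overlapping neighborhoods (Jaccard weight on the k+1-neighborhoods
including self, pruned below 1/15), Leiden modularity communities
(RBConfiguration) at resolution 0.25 with a fixed seed. The SNN
construction connects all pairs with common neighbors rather than only kNN
pairs; the denser graph anchors boundary cells to their own population,
which matters because the classification rule is all-or-nothing: an
experimental doublet is *biological* iff its cluster contains zero
synthetic cells, *artifactual* otherwise.

### Differential expression

Wilcoxon rank-sum per gene on log-normalized expression,
log2FC = log2((mean expm1 + 1)/(mean expm1 + 1)), Benjamini–Hochberg
adjustment, rows sorted by adjusted p then |log2FC|. Groups under 3 cells
trigger a reliability warning. A per-cluster experimental-vs-synthetic
comparison within mixed clusters is provided as a misclassification check —
those two groups should look alike.

### Spatial co-localization

A spot co-localizes types A and B when each contributes at least 10% of the
spot's summed cell-type scores (spots with zero total are never flagged).
The permutation null shuffles every score column independently across spots
(a permutation, so each column's multiset is exact) and recomputes the
rate; add-one tail p-values are reported for both tails because real slides
can sit *below* the null — compositional anti-correlation between types is
the default in mixtures, and above-null co-localization requires genuine
joint enrichment. Moran's I is computed on the binary flags with hex
lattice weights (neighbors at array offsets (0, ±2) and (±1, ±1), w = 1)
and a Monte-Carlo permutation p (999 draws, tail chosen by the side of
−1/(N−1) the observed value falls on). I is undefined for constant flags
(returned as NaN with a warning).

## Quality control and normalization

Raw matrices are filtered in a fixed order: (1) cells above the
mitochondrial-fraction cap (default 5%; 10% suits datasets sensitive to
this filter), (2) genes detected in fewer than 10 cells, (3) cells with
fewer than 100 detected genes. The order is a documented choice; the rules
are idempotent in combination. Normalization is ln(1 + count/total ×
10 000); z-scaling is applied only for clustering input, never for set
scoring. Spatial counts use the same normalization — rank-based set scoring
is robust to the choice of variance-stabilization scheme, so no separate
spatial normalization is implemented.

## Simulated data

The generator produces the minimal structure the pipeline assumes, not a
calibrated replica of any real dataset.

* **Counts**: negative binomial, dispersion 0.5 (var = μ + 0.5μ²), gene
  means log-normal around `base_rate` = 2 (σ_log = 0.4).
* **Cell types**: 3 types × 200 cells by default; 20 marker genes per type
  at 24× their base mean in the owning type and 0.05× elsewhere. Marker
  dominance at this level mirrors canonical markers (Cd3e, Lyz2, Ncr1 …),
  and keeps doublets callable: each half's markers must stay above the
  scoring thresholds after the doublet's depth roughly doubles.
* **Doublets**: artifactual = exact sum of a random focal-A and focal-B
  singlet column; biological = the same sum with 20 dedicated interaction
  genes multiplied by 4. Interaction genes have a common base mean of 16 —
  they emulate abundant inducible immune genes (chemokines, MHC class I),
  which are among the highest-expressed genes in activated cells. At low
  expression a 4× effect on 20 genes would be neither recoverable by the
  fixed clustering parameters nor representative of the genes this kind of
  analysis reports.
* **CITE counts**: NB with mean 60 on a cell's own type markers (both for
  doublets) and 2 elsewhere.
* **Slides**: spots on the Visium parity lattice (row+col even). Each spot
  has an immune fraction f (Beta around 0.15, concentration 300) split
  between the two focal types by a symmetric Beta(8, 8); the remaining mass
  is divided among other types by a flat Dirichlet. A hotspot region
  multiplies the odds of f by `enrichment` (default 12), co-enriching the
  focal pair — joint infiltration, the only signal the permutation test can
  see, since independent marginal enrichment is preserved under column
  permutation. Spot counts are NB mixtures of the type profiles at ~3000
  expected counts.

**What passing tests show — and do not.** The simulations demonstrate
internal correctness (rules implemented as stated, planted structure
recovered, permutation tests calibrated on null inputs). They do not show
that real doublets separate this cleanly: real data carry correlated
nuisance variation (cell cycle, stress, ambient RNA), unmodeled here, and
real interaction programs are not 20 equal-effect genes. The no-hotspot
slides show below-null co-localization (compositional anti-correlation),
so permutation-test calibration is demonstrated on iid-score slides, where
exchangeability holds by construction.

## Numerical and design choices

* Gene-set construction uses mean-CPM log2 fold-changes with pseudocount 1
  rather than a count-model DE fit: downstream consumes only (gene, logFC)
  pairs, and the simpler statistic is deterministic and library-size
  invariant. No p-value gate is applied; the fold-change cutoff (5 for
  cells, 3 for the sparser spots) is the only admission rule.
* The scoring null uses one permuted matrix by default; pooling across
  cells gives n_cells draws, which is ample for a two-parameter gamma fit.
  The per-set RNG stream is derived from (seed, set index).
* k-means gating runs on CLR values, not raw counts — raw CITE counts are
  heavy-tailed and a 2-means split on them is dominated by the largest
  cell.
* Tie-breaks: the most frequent doublet pair is chosen with lexicographic
  order on ties; het-doublet pair labels are stored sorted.
* The permutation and Monte-Carlo p-values use the add-one estimator, so
  the smallest attainable p is 1/(1+n); with 199 permutations the 0.05
  level is exactly attainable (10/200).
* Calibration experiments use 2000-spot slides, matching the 1263–3107
  spots of real Visium tissue sections; at a few hundred spots the discrete
  tie structure of rates makes the add-one estimator visibly conservative.
* Moran's I Monte-Carlo p is one-sided on the side of the null expectation
  −1/(N−1) where the observed value falls.

## Problem sizes

Default test and acceptance runs use 1000 genes × 1000 cells for the
single-cell path (200 cells per type, 200 + 200 planted doublets, 200
synthetic), 900-spot slides for power and 2000-spot score matrices for
calibration (400 slides × 199 permutations). These sizes give stable
recovery statistics while keeping a full run in tens of seconds.

## Known limitations

* Homotypic doublets and higher-order multiplets are out of reach of the
  calling rule by design; multiplets are recorded and excluded.
* The zero-synthetic purity rule is a cliff: one mislabeled boundary cell
  flips an entire cluster from biological to artifactual. The dense SNN
  graph mitigates this; it cannot eliminate it. Resampled-mode synthetic
  doublets sharing a parent cell form correlated cliques that are more
  likely to cross the boundary — unique mode is preferred for separation.
* A biological doublet dominated by one partner (extreme depth imbalance)
  can pass the singleton rule and poison the synthetic pool with
  interaction-bearing "singletons". At realistic doublet prevalence this
  is rare, but it is the mechanism to suspect when a well-supported
  biological cluster vanishes after re-running with different seeds.
* Gene-set weights come from bulk-style references; cell types absent from
  the reference are invisible, and sets that lose all genes to matrix
  filtering are dropped with a warning.
* The spatial analysis treats spot scores as composition proxies; it does
  not deconvolve spot mixtures.
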