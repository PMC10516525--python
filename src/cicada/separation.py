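"""Separate biological from artifactual doublets via synthetic-doublet clustering.

Candidate (experimental) doublets and synthetic doublets are merged,
filtered, embedded with PCA and clustered on a shared-nearest-neighbor
graph.  A cluster containing zero synthetic cells is evidence that its
members carry expression the non-interacting null cannot produce: every
experimental cell in such a cluster is classified biological, while
experimental cells sharing a cluster with synthetic doublets are classified
artifactual.  Differential expression between groups then characterizes the
interaction signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from cicada.io_formats import (
    DEFAULT_MITO_PATTERN,
    DEFAULT_RIBO_PATTERN,
    CellExpressionMatrix,
    lognormalize,
)
from cicada.doublets import SyntheticDoubletSet

import re


@dataclass
class SeparationParams:
    """Clustering parameters: cells need >= 100 genes, genes need presence in
    >= 50% of each object's cells, PCA to 30 components, SNN graph on k = 20
    neighbors, modularity communities at resolution 0.25."""

    min_genes_per_cell: int = 100
    min_cell_fraction_per_gene: float = 0.5
    n_pcs: int = 30
    n_neighbors: int = 20
    cluster_resolution: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_cell_fraction_per_gene <= 1:
            raise ValueError("min_cell_fraction_per_gene must lie in (0, 1]")


@dataclass
class SeparationResult:
    """Per merged cell: origin, cluster and biological/artifactual/synthetic call."""

    table: pd.DataFrame  # cell_id, origin, cluster, classification
    embedding: np.ndarray | None = None

    def biological_ids(self) -> np.ndarray:
        t = self.table
        return t.loc[t["classification"] == "biological", "cell_id"].to_numpy(object)

    def artifactual_ids(self) -> np.ndarray:
        t = self.table
        return t.loc[t["classification"] == "artifactual", "cell_id"].to_numpy(object)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _object_filter(m: CellExpressionMatrix, p: SeparationParams) -> CellExpressionMatrix:
    """Within one object: keep cells with >= min genes, then genes present in
    >= min_cell_fraction of that object's cells ("present" = nonzero count)."""
    detected = m.counts > 0
    keep_cells = np.asarray(detected.sum(axis=0)).ravel() >= p.min_genes_per_cell
    m = m.subset(cell_mask=keep_cells)
    if m.n_cells == 0:
        raise ValueError("no cells left after per-object gene-count filter")
    frac = np.asarray((m.counts > 0).sum(axis=1)).ravel() / m.n_cells
    return m.subset(gene_mask=frac >= p.min_cell_fraction_per_gene)


def merge_and_filter(
    true_doublets: CellExpressionMatrix,
    synth: SyntheticDoubletSet | CellExpressionMatrix,
    p: SeparationParams | None = None,
    mito_pattern: str = DEFAULT_MITO_PATTERN,
    ribo_pattern: str = DEFAULT_RIBO_PATTERN,
) -> tuple[CellExpressionMatrix, np.ndarray]:
    """Filter each object, merge on the gene intersection, drop mito/ribo genes.

    Returns the merged matrix and an origin label per cell
    ("experimental" / "synthetic").  Filtering is per object BEFORE the
    merge; mitochondrial and ribosomal genes are removed after it.
    """
    p = p or SeparationParams()
    synth_m = synth.counts if isinstance(synth, SyntheticDoubletSet) else synth
    a = _object_filter(true_doublets, p)
    b = _object_filter(synth_m, p)
    shared = [g for g in a.gene_ids if g in set(b.gene_ids.tolist())]
    if not shared:
        raise ValueError("empty gene intersection between objects")
    a_idx = {g: i for i, g in enumerate(a.gene_ids)}
    b_idx = {g: i for i, g in enumerate(b.gene_ids)}
    ga = np.array([a_idx[g] for g in shared])
    gb = np.array([b_idx[g] for g in shared])
    merged_counts = sp.hstack([a.counts[ga], b.counts[gb]]).tocsc()
    cell_ids = np.concatenate([a.cell_ids, b.cell_ids])
    origin = np.array(
        ["experimental"] * a.n_cells + ["synthetic"] * b.n_cells, dtype=object
    )
    rx_m, rx_r = re.compile(mito_pattern), re.compile(ribo_pattern)
    keep = np.array(
        [not (rx_m.search(str(g)) or rx_r.search(str(g))) for g in shared], dtype=bool
    )
    merged = CellExpressionMatrix(
        merged_counts[np.where(keep)[0]],
        np.asarray(shared, dtype=object)[keep],
        cell_ids,
    )
    return merged, origin


def snn_graph(pcs: np.ndarray, n_neighbors: int = 20, prune: float = 1 / 15) -> ig.Graph:
    """Shared-nearest-neighbor graph in PC space.

    Every pair of cells with overlapping k-nearest-neighborhoods (self
    included) is connected with weight |kNN(i) ∩ kNN(j)| / |kNN(i) ∪ kNN(j)|
    (neighborhood Jaccard); weights below ``prune`` are dropped.  This is
    the construction popular single-cell toolkits use upstream of
    modularity clustering.
    """
    n = pcs.shape[0]
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)  # includes self at position 0
    rows = np.repeat(np.arange(n), k + 1)
    member = sp.csr_matrix(
        (np.ones((k + 1) * n), (rows, idx.ravel())), shape=(n, n)
    )
    inter = (member @ member.T).tocoo()  # |N(i) & N(j)|
    mask = inter.row < inter.col
    i_, j_, shared = inter.row[mask], inter.col[mask], inter.data[mask]
    jac = shared / (2 * (k + 1) - shared)
    keep = jac >= prune
    g = ig.Graph(n=n, edges=list(zip(i_[keep].tolist(), j_[keep].tolist())))
    g.es["weight"] = jac[keep].tolist()
    return g


def cluster_doublets(
    merged: CellExpressionMatrix,
    origin: np.ndarray,
    p: SeparationParams | None = None,
    compute_embedding: bool = False,
) -> SeparationResult:
    """Cluster the merged doublets and classify experimental cells.

    Pipeline: log-normalize, per-gene z-scale, PCA to ``n_pcs`` (reduced
    with a warning when there are fewer cells), SNN graph on ``n_neighbors``
    nearest neighbors, modularity community detection (RBConfiguration /
    Leiden) at ``cluster_resolution`` with a fixed seed.  Experimental cells
    in clusters free of synthetic cells are biological; the rest are
    artifactual.
    """
    p = p or SeparationParams()
    origin = np.asarray(origin, dtype=object)
    norm = lognormalize(merged.counts, zscale=True)
    n_pcs = p.n_pcs
    n_cells = merged.n_cells
    max_pcs = min(n_cells - 1, merged.n_genes)
    if n_pcs > max_pcs:
        warnings.warn(f"n_pcs reduced from {n_pcs} to {max_pcs} (too few cells/genes)")
        n_pcs = max_pcs
    pca = PCA(n_components=n_pcs, random_state=p.seed)
    pcs = pca.fit_transform(norm.T)

    g = snn_graph(pcs, p.n_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=p.cluster_resolution,
        seed=p.seed,
        n_iterations=-1,
    )
    clusters = np.asarray(part.membership)

    classification = np.empty(n_cells, dtype=object)
    for c in np.unique(clusters):
        members = clusters == c
        has_synth = np.any(origin[members] == "synthetic")
        for i in np.where(members)[0]:
            if origin[i] == "synthetic":
                classification[i] = "synthetic"
            elif has_synth:
                classification[i] = "artifactual"
            else:
                classification[i] = "biological"

    embedding = pcs[:, :2].copy() if compute_embedding else None
    table = pd.DataFrame(
        {
            "cell_id": merged.cell_ids,
            "origin": origin,
            "cluster": clusters,
            "classification": classification,
        }
    )
    return SeparationResult(table, embedding)


@dataclass
class DETable:
    """Per-gene differential-expression results, BH-adjusted, sorted by
    adjusted p then |log2FC|."""

    table: pd.DataFrame

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["adjusted_p"] < alpha]

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def differential_expression(
    merged: CellExpressionMatrix,
    group1: np.ndarray,
    group2: np.ndarray,
    group_labels: tuple[str, str] = ("group1", "group2"),
) -> DETable:
    """Wilcoxon rank-sum DE between two cell groups on log-normalized data.

    log2FC compares group means on the natural count scale:
    log2((mean(expm1 x) + 1 in group1) / (mean(expm1 x) + 1 in group2));
    p-values are Benjamini-Hochberg adjusted.  Groups smaller than 3 cells
    trigger a reliability warning.
    """
    g1 = np.asarray(group1, dtype=object)
    g2 = np.asarray(group2, dtype=object)
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both groups must be nonempty")
    if len(g1) < 3 or len(g2) < 3:
        warnings.warn("group of size < 3: rank-sum p-values unreliable")
    idx = {c: i for i, c in enumerate(merged.cell_ids)}
    i1 = np.array([idx[c] for c in g1])
    i2 = np.array([idx[c] for c in g2])
    norm = lognormalize(merged.counts)
    x1, x2 = norm[:, i1], norm[:, i2]

    mean1 = np.expm1(x1).mean(axis=1)
    mean2 = np.expm1(x2).mean(axis=1)
    log2fc = np.log2((mean1 + 1) / (mean2 + 1))
    pct1 = (x1 > 0).mean(axis=1)
    pct2 = (x2 > 0).mean(axis=1)

    pvals = np.ones(merged.n_genes)
    expressed = (mean1 > 0) | (mean2 > 0)
    if expressed.any():
        res = scipy.stats.mannwhitneyu(
            x1[expressed], x2[expressed], axis=1, alternative="two-sided"
        )
        pvals[expressed] = res.pvalue
    adj = multipletests(pvals, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "gene": merged.gene_ids,
            "log2FC": log2fc,
            "p_value": pvals,
            "adjusted_p": adj,
            "pct_group1": pct1,
            "pct_group2": pct2,
            "group_label": f"{group_labels[0]}_vs_{group_labels[1]}",
        }
    )
    table = table.sort_values(
        ["adjusted_p", "log2FC"], key=lambda s: s if s.name == "adjusted_p" else -s.abs()
    ).reset_index(drop=True)
    return DETable(table)


def per_cluster_de(
    merged: CellExpressionMatrix,
    result: SeparationResult,
    min_group: int = 3,
) -> dict[int, DETable]:
    """Within each mixed cluster: experimental-vs-synthetic DE (a clustering
    misidentification check: the two groups should look alike)."""
    out: dict[int, DETable] = {}
    t = result.table
    for c in sorted(t["cluster"].unique()):
        sub = t[t["cluster"] == c]
        exp = sub.loc[sub["origin"] == "experimental", "cell_id"].to_numpy(object)
        syn = sub.loc[sub["origin"] == "synthetic", "cell_id"].to_numpy(object)
        if len(exp) >= min_group and len(syn) >= min_group:
            out[int(c)] = differential_expression(
                merged, exp, syn, ("experimental", "synthetic")
            )
    return out
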