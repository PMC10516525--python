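"""Multi-label cell-type scoring (CAMML) and CITE-seq gating (ChIMP).

Each cell receives, per weighted gene set, a score in [0, 1]: the
variance-adjusted squared distance of the cell's normalized expression on
the set genes from the origin, mapped through the CDF of a gamma fit to a
permutation null.  With CITE-seq data the scores are gated: a cell keeps a
cell type's score only if a k=2 k-means split of the CLR-normalized counts
of one of that type's surface markers places the cell in the higher
(positive) cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.cluster import KMeans

from cicada.io_formats import AntibodyCaptureMatrix, SpatialSlide, clr_normalize, lognormalize
from cicada.reference_sets import WeightedGeneSet

VARIANCE_FLOOR = 1e-8


@dataclass
class CellTypeScoreMatrix:
    """Cells x cell types, every entry in [0, 1]."""

    scores: np.ndarray
    cell_ids: np.ndarray
    cell_types: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.cell_types = np.asarray(self.cell_types, dtype=object)
        if self.scores.shape != (len(self.cell_ids), len(self.cell_types)):
            raise ValueError("score matrix shape mismatch")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("scores must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.cell_ids, columns=self.cell_types)

    def column(self, cell_type: str) -> np.ndarray:
        idx = np.where(self.cell_types == cell_type)[0]
        if len(idx) == 0:
            raise KeyError(f"unknown cell type: {cell_type}")
        return self.scores[:, idx[0]]


@dataclass
class MarkerRule:
    """One surface marker gating a cell type; ``invert`` for negative markers
    (e.g. CD45- endothelial cells: positive means the LOWER k-means cluster)."""

    marker: str
    invert: bool = False


@dataclass
class MarkerMap:
    """cell type -> surface markers, combined with "any" logic.

    A cell is gate-positive for a type if at least one of the type's marker
    rules calls it positive (e.g. T cells: CD4+ OR CD8+).
    """

    rules: dict[str, list[MarkerRule]] = field(default_factory=dict)

    def add(self, cell_type: str, marker: str, invert: bool = False) -> "MarkerMap":
        self.rules.setdefault(cell_type, []).append(MarkerRule(marker, invert))
        return self

    def markers(self) -> list[str]:
        return sorted({r.marker for rules in self.rules.values() for r in rules})


def _null_distances(
    x: np.ndarray,
    inv_var_weighted: np.ndarray,
    set_gene_ids: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Distances after independently permuting each gene's values across cells.

    Genes are visited in sorted-ID order and each gene's values are sorted
    before the seeded permutation is applied, so the null (and hence the
    scores) is invariant to the ordering of cells and genes in the input.
    """
    order = np.argsort(set_gene_ids.astype(str))
    n = x.shape[0]
    chunks = []
    for _ in range(n_perm):
        d = np.zeros(n)
        for j in order:
            null_col = np.sort(x[:, j])[rng.permutation(n)]
            d += (null_col**2) * inv_var_weighted[j]
        chunks.append(d)
    return np.concatenate(chunks)


def _gamma_cdf_scores(d: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Method-of-moments gamma fit to the nonzero null distances, then CDF."""
    nz = null[null > 0]
    if nz.size < 2 or nz.var() == 0:
        # degenerate null: no spread to calibrate against
        return (d > 0).astype(float)
    mean, var = nz.mean(), nz.var()
    shape = mean**2 / var
    scale = var / mean
    return np.clip(scipy.stats.gamma.cdf(d, a=shape, scale=scale), 0.0, 1.0)


def vam_score(
    norm_expr: np.ndarray,
    gene_ids: np.ndarray,
    cell_ids: np.ndarray,
    sets: list[WeightedGeneSet],
    n_null_perm: int = 1,
    seed: int = 0,
) -> CellTypeScoreMatrix:
    """Score cells against weighted gene sets (variance-adjusted Mahalanobis).

    Parameters
    ----------
    norm_expr
        Log-normalized (NOT z-scaled) expression, genes x cells, dense.
    sets
        Weighted gene sets; genes absent from ``gene_ids`` are dropped with
        a warning, and a set that loses all its genes is dropped entirely.
    n_null_perm
        Number of full permuted matrices pooled into the null (>= 1).

    Notes
    -----
    Per cell i and set S the squared adjusted distance from the origin is
    ``d_i = sum_{g in S} w~_g * x_ig^2 / v_g`` with v_g the per-gene variance
    across cells (floored at 1e-8) and w~ the set weights rescaled to sum to
    |S|.  The null permutes each gene's values independently across cells;
    a gamma distribution fit by method of moments to the pooled nonzero null
    distances maps d to a [0, 1] score via its CDF.
    """
    if n_null_perm < 1:
        raise ValueError("n_null_perm must be >= 1")
    norm_expr = np.asarray(norm_expr, dtype=float)
    gene_ids = np.asarray(gene_ids, dtype=object)
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    n_cells = norm_expr.shape[1]
    cols: list[np.ndarray] = []
    kept_types: list[str] = []
    for set_idx, s in enumerate(sets):
        rng = np.random.default_rng([seed, set_idx])  # per-set stream
        present = np.array([g in gene_index for g in s.genes], dtype=bool)
        if not present.all():
            warnings.warn(
                f"{(~present).sum()} gene(s) of set {s.cell_type} absent from matrix"
            )
        if not present.any():
            warnings.warn(f"set {s.cell_type} has no genes in the matrix; dropped")
            continue
        idx = np.array([gene_index[g] for g in s.genes[present]])
        w = s.weights[present]
        w = w / w.sum() * len(w)  # normalize weights to sum to |S|
        x = norm_expr[idx].T  # cells x set genes
        var = np.maximum(x.var(axis=0), VARIANCE_FLOOR)
        inv_var_weighted = w / var
        d = (x**2) @ inv_var_weighted
        if not np.any(x):
            cols.append(np.zeros(n_cells))
            kept_types.append(s.cell_type)
            continue
        null = _null_distances(x, inv_var_weighted, s.genes[present], n_null_perm, rng)
        cols.append(_gamma_cdf_scores(d, null))
        kept_types.append(s.cell_type)
    scores = np.column_stack(cols) if cols else np.zeros((n_cells, 0))
    return CellTypeScoreMatrix(scores, cell_ids, np.array(kept_types, dtype=object))


def kmeans_positive(values: np.ndarray, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """Split 1-D values into high/low by k=2 k-means; True = higher-centroid cluster."""
    v = np.asarray(values, dtype=float).reshape(-1, 1)
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed).fit(v)
    hi = int(np.argmax(km.cluster_centers_.ravel()))
    return km.labels_ == hi


def chimp_gate(
    scores: CellTypeScoreMatrix,
    cite: AntibodyCaptureMatrix,
    marker_map: MarkerMap,
    seed: int = 0,
) -> CellTypeScoreMatrix:
    """Zero out cell-type scores for cells negative on all of the type's markers.

    Each marker's CLR-normalized counts are split by 1-D k=2 k-means;
    membership in the higher-centroid cluster means marker-positive (the
    lower cluster for inverted/negative markers).  A cell keeps its score
    for type T iff at least one of T's marker rules calls it positive;
    otherwise the score becomes exactly 0.  Markers with constant counts
    across cells are skipped with a warning (the split is degenerate).
    Cell types without an entry in the map pass through ungated.
    """
    if not np.array_equal(scores.cell_ids, cite.cell_ids):
        raise ValueError("score matrix and antibody matrix cell_ids differ")
    if cite.n_markers > 1:
        clr = clr_normalize(cite)
    else:
        # CLR is identically zero for a single-marker panel; gate on ln(1+x)
        clr = np.log1p(np.asarray(cite.counts.todense(), dtype=float))
    marker_index = {m: i for i, m in enumerate(cite.marker_ids)}
    positive: dict[str, np.ndarray] = {}
    for marker in marker_map.markers():
        if marker not in marker_index:
            raise KeyError(f"marker {marker} not in antibody capture matrix")
        vals = clr[marker_index[marker]]
        if np.all(vals == vals[0]):
            warnings.warn(f"marker {marker} has constant counts; gate skipped")
            continue
        positive[marker] = kmeans_positive(vals, seed=seed)

    gated = scores.scores.copy()
    for t, ct in enumerate(scores.cell_types):
        rules = marker_map.rules.get(str(ct))
        if not rules:
            continue
        usable = [r for r in rules if r.marker in positive]
        if not usable:
            continue  # all markers degenerate -> ungated
        keep = np.zeros(len(scores.cell_ids), dtype=bool)
        for r in usable:
            keep |= ~positive[r.marker] if r.invert else positive[r.marker]
        gated[~keep, t] = 0.0
    return CellTypeScoreMatrix(gated, scores.cell_ids, scores.cell_types)


def score_spots(
    slide: SpatialSlide,
    sets: list[WeightedGeneSet],
    n_null_perm: int = 1,
    seed: int = 0,
) -> CellTypeScoreMatrix:
    """Score Visium spots with the same set-scoring algorithm used on cells.

    Spots are depth-normalized and log-transformed first; only in-tissue
    spots are scored.  Spatial gene sets are normally built with the lower
    log2 fold-change cutoff (3) to tolerate spot-level sparsity.
    """
    tissue = slide.tissue_subset()
    norm = lognormalize(tissue.counts, cell_axis=0).T  # genes x spots
    return vam_score(norm, tissue.gene_ids, tissue.spot_ids, sets, n_null_perm, seed)


def write_scores(scores: CellTypeScoreMatrix, path) -> None:
    scores.to_frame().rename_axis("cell_id").to_csv(path, sep="\t")


def read_scores(path) -> CellTypeScoreMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CellTypeScoreMatrix(
        df.to_numpy(float),
        df.index.to_numpy(object),
        df.columns.to_numpy(object),
    )
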