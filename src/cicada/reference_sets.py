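"""Weighted cell-type gene sets from a labeled reference expression matrix.

Sets are built one-vs-all: a gene enters the set for cell type T when its
log2 fold-change of mean CPM in T samples over non-T samples (pseudocount 1)
exceeds the cutoff, and its weight is that log2 fold-change.  The default
cutoff is 5 for scRNA-seq scoring and 3 for the sparser Visium spots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SCRNA_LOGFC_CUTOFF = 5.0
SPATIAL_LOGFC_CUTOFF = 3.0


@dataclass
class WeightedGeneSet:
    """A cell type's marker genes with positive log2 fold-change weights."""

    cell_type: str
    genes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.genes) != len(self.weights):
            raise ValueError("genes and weights lengths differ")
        if len(self.genes) == 0:
            raise ValueError(f"empty gene set for {self.cell_type}")
        if len(set(self.genes.tolist())) != len(self.genes):
            raise ValueError(f"duplicate genes in set {self.cell_type}")
        if np.any(self.weights <= 0):
            raise ValueError(f"non-positive weight in set {self.cell_type}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ReferenceMatrix:
    """Bulk-style reference: genes x labeled samples, >= 2 distinct labels."""

    expr: np.ndarray
    gene_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.expr.shape != (len(self.gene_ids), len(self.labels)):
            raise ValueError("reference expression shape mismatch")
        if not np.all(np.isfinite(self.expr)) or np.any(self.expr < 0):
            raise ValueError("reference expression must be finite and non-negative")
        if len(set(self.labels.tolist())) < 2:
            raise ValueError("reference needs at least 2 distinct cell-type labels")


def build_gene_sets(
    ref: ReferenceMatrix,
    logfc_cutoff: float = SCRNA_LOGFC_CUTOFF,
    pseudocount: float = 1.0,
) -> list[WeightedGeneSet]:
    """One-vs-all weighted gene sets from a labeled reference.

    Per cell type T and gene g:
    logFC(g) = log2((mean CPM in T + c) / (mean CPM outside T + c)), c the
    pseudocount.  Genes with logFC > ``logfc_cutoff`` form T's set, weighted
    by logFC.  Cell types whose set comes out empty are dropped with a
    warning.
    """
    if logfc_cutoff <= 0:
        raise ValueError("logfc_cutoff must be positive")
    totals = ref.expr.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("reference sample with zero total expression")
    cpm = ref.expr / totals[None, :] * 1e6
    sets: list[WeightedGeneSet] = []
    for ct in sorted(set(ref.labels.tolist())):
        in_t = ref.labels == ct
        logfc = np.log2(
            (cpm[:, in_t].mean(axis=1) + pseudocount)
            / (cpm[:, ~in_t].mean(axis=1) + pseudocount)
        )
        keep = logfc > logfc_cutoff
        if not keep.any():
            warnings.warn(f"no genes pass logFC > {logfc_cutoff} for {ct}; set dropped")
            continue
        sets.append(WeightedGeneSet(ct, ref.gene_ids[keep], logfc[keep]))
    return sets


def write_gene_sets(sets: list[WeightedGeneSet], path: str | Path) -> None:
    """Write sets as a TSV with columns cell_type, gene, weight."""
    rows = [
        {"cell_type": s.cell_type, "gene": g, "weight": w}
        for s in sets
        for g, w in zip(s.genes, s.weights)
    ]
    pd.DataFrame(rows, columns=["cell_type", "gene", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_sets(path: str | Path) -> list[WeightedGeneSet]:
    """Read a gene-set TSV (cell_type, gene, weight); weights must be > 0."""
    df = pd.read_csv(path, sep="\t")
    missing = {"cell_type", "gene", "weight"} - set(df.columns)
    if missing:
        raise ValueError(f"gene-set file missing columns: {sorted(missing)}")
    if (df["weight"] <= 0).any():
        bad = df.loc[df["weight"] <= 0].iloc[0]
        raise ValueError(f"non-positive weight for gene {bad['gene']} in {bad['cell_type']}")
    return [
        WeightedGeneSet(ct, grp["gene"].to_numpy(object), grp["weight"].to_numpy(float))
        for ct, grp in df.groupby("cell_type", sort=True)
    ]
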