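"""Doublet calling from cell-type scores and synthetic-doublet construction.

Calling rules (score thresholds tau_hi = 0.75, tau_lo = 0.5):

* heterotypic doublet — exactly two cell types score above tau_hi;
* multiplet — more than two types above tau_hi (recorded, excluded
  downstream; homotypic doublets are inherently not callable this way);
* high-confidence singleton — exactly one type above tau_hi and every other
  type at or below tau_lo;
* everything else — unassigned.

Synthetic doublets are elementwise sums of the raw counts of two
high-confidence singletons of the two focal types: the non-interacting null
against which candidate doublets are clustered.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from cicada.io_formats import CellExpressionMatrix
from cicada.scoring import CellTypeScoreMatrix


@dataclass
class CallThresholds:
    """Score cut-offs: tau_hi admits a type call, tau_lo caps the off-target
    scores a singleton may carry."""

    tau_hi: float = 0.75
    tau_lo: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.tau_lo <= self.tau_hi < 1):
            raise ValueError("need 0 < tau_lo <= tau_hi < 1")


@dataclass
class DoubletCallTable:
    """Per-cell call with the scores that triggered it.

    ``table`` columns: cell_id, status (singleton | het_doublet | multiplet |
    unassigned), type1, type2, score1, score2.  For het_doublets the type
    pair is unordered and stored lexicographically.
    """

    table: pd.DataFrame
    thresholds: CallThresholds

    def of_status(self, status: str) -> pd.DataFrame:
        return self.table[self.table["status"] == status]

    def singletons_of(self, cell_type: str) -> np.ndarray:
        t = self.table
        m = (t["status"] == "singleton") & (t["type1"] == cell_type)
        return t.loc[m, "cell_id"].to_numpy(object)

    def het_doublets_of(self, type_a: str, type_b: str) -> np.ndarray:
        a, b = sorted([type_a, type_b])
        t = self.table
        m = (t["status"] == "het_doublet") & (t["type1"] == a) & (t["type2"] == b)
        return t.loc[m, "cell_id"].to_numpy(object)

    def pair_counts(self) -> pd.Series:
        d = self.of_status("het_doublet")
        return d.groupby(["type1", "type2"]).size().sort_values(ascending=False)

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def call_cells(
    scores: CellTypeScoreMatrix, th: CallThresholds | None = None
) -> DoubletCallTable:
    """Classify every cell as singleton / het_doublet / multiplet / unassigned."""
    th = th or CallThresholds()
    s = scores.scores
    types = scores.cell_types
    hi = s > th.tau_hi
    n_hi = hi.sum(axis=1)

    rows = []
    for i, cell in enumerate(scores.cell_ids):
        if n_hi[i] == 2:
            j1, j2 = np.where(hi[i])[0]
            (a, sa), (b, sb) = sorted(
                [(str(types[j1]), s[i, j1]), (str(types[j2]), s[i, j2])],
                key=lambda p: p[0],
            )
            rows.append((cell, "het_doublet", a, b, sa, sb))
        elif n_hi[i] > 2:
            order = np.argsort(s[i])[::-1][:2]
            rows.append(
                (cell, "multiplet", str(types[order[0]]), str(types[order[1]]),
                 s[i, order[0]], s[i, order[1]])
            )
        elif n_hi[i] == 1:
            j = int(np.where(hi[i])[0][0])
            others = np.delete(s[i], j)
            if others.size == 0 or others.max() <= th.tau_lo:
                rows.append((cell, "singleton", str(types[j]), "", s[i, j], np.nan))
            else:
                rows.append((cell, "unassigned", "", "", s[i, j], np.nan))
        else:
            top = s[i].max() if s.shape[1] else np.nan
            rows.append((cell, "unassigned", "", "", top, np.nan))
    table = pd.DataFrame(
        rows, columns=["cell_id", "status", "type1", "type2", "score1", "score2"]
    )
    return DoubletCallTable(table, th)


def select_pair(calls: DoubletCallTable) -> tuple[str, str]:
    """The most frequent heterotypic doublet type pair (lexicographic tie-break)."""
    counts = calls.pair_counts()
    if counts.empty:
        raise ValueError("no heterotypic doublets called")
    best = counts[counts == counts.max()]
    return sorted(best.index.tolist())[0]


@dataclass
class SyntheticDoubletSet:
    """In-silico doublets: each column the sum of two source singletons' raw counts."""

    counts: CellExpressionMatrix
    provenance: pd.DataFrame  # synthetic_id, source_a, source_b
    mode: str
    seed: int

    @property
    def n_doublets(self) -> int:
        return self.counts.n_cells

    def write(self, directory: str | Path) -> None:
        from cicada.io_formats import write_10x_counts

        directory = Path(directory)
        write_10x_counts(self.counts, directory)
        self.provenance.to_csv(directory / "provenance.tsv", sep="\t", index=False)


def make_synthetic_doublets(
    m: CellExpressionMatrix,
    singletons_a: np.ndarray,
    singletons_b: np.ndarray,
    mode: str = "unique",
    n_resampled: int = 1000,
    seed: int = 0,
) -> SyntheticDoubletSet:
    """Sum raw counts of randomly paired singletons of the two focal types.

    ``unique`` mode shuffles both lists and pairs the first
    ``min(|A|, |B|)`` of each, so no source cell is reused and the yield is
    capped by the smaller singleton population.  ``resampled`` mode draws
    ``n_resampled`` (a, b) pairs uniformly with replacement, decoupling the
    yield from population sizes.  Synthetic cell IDs encode provenance.
    """
    singletons_a = np.asarray(singletons_a, dtype=object)
    singletons_b = np.asarray(singletons_b, dtype=object)
    if len(singletons_a) == 0 or len(singletons_b) == 0:
        raise ValueError("both singleton lists must be nonempty")
    if set(singletons_a) & set(singletons_b):
        raise ValueError("singleton lists must be disjoint")
    cell_index = {c: i for i, c in enumerate(m.cell_ids)}
    missing = [c for c in np.concatenate([singletons_a, singletons_b]) if c not in cell_index]
    if missing:
        raise KeyError(f"singleton cell(s) not in matrix: {missing[:5]}")

    rng = np.random.default_rng(seed)
    if mode == "unique":
        a = rng.permutation(singletons_a)
        b = rng.permutation(singletons_b)
        k = min(len(a), len(b))
        pairs = list(zip(a[:k], b[:k]))
    elif mode == "resampled":
        pairs = [
            (rng.choice(singletons_a), rng.choice(singletons_b))
            for _ in range(n_resampled)
        ]
    else:
        raise ValueError(f"unknown mode: {mode!r}")

    ia = np.array([cell_index[a] for a, _ in pairs])
    ib = np.array([cell_index[b] for _, b in pairs])
    counts = m.counts[:, ia] + m.counts[:, ib]
    ids = np.array([f"synth_{i}|{a}+{b}" for i, (a, b) in enumerate(pairs)], dtype=object)
    prov = pd.DataFrame(
        {"synthetic_id": ids, "source_a": [a for a, _ in pairs], "source_b": [b for _, b in pairs]}
    )
    synth = CellExpressionMatrix(sp.csc_matrix(counts), m.gene_ids, ids)
    return SyntheticDoubletSet(synth, prov, mode, seed)
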