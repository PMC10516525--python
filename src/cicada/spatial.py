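"""Spatial co-localization of two cell types on Visium slides.

A spot co-localizes the focal types A and B when each contributes at least
``frac`` (default 10%) of the spot's summed cell-type scores.  The observed
co-localization rate is tested against a null built by permuting every
cell-type score column independently across spots; Moran's I on the binary
co-localization flags quantifies whether co-localized spots aggregate
spatially on the hexagonal lattice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from cicada.io_formats import SpatialSlide
from cicada.scoring import CellTypeScoreMatrix

# Visium hex lattice: six neighbors at these (row, col) array offsets
HEX_OFFSETS = ((0, 2), (0, -2), (1, 1), (1, -1), (-1, 1), (-1, -1))


@dataclass
class ColocResult:
    """Observed rate, permutation null, tail p-values and Moran's I."""

    coloc: np.ndarray  # boolean per spot
    rate: float
    perm_rates: np.ndarray
    p_upper: float
    p_lower: float
    morans_i: float | None = None
    morans_p: float | None = None
    frac_threshold: float = 0.10
    n_perm: int = 1000
    seed: int = 0
    spot_ids: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "rate": self.rate,
            "p_upper": self.p_upper,
            "p_lower": self.p_lower,
            "morans_i": self.morans_i,
            "morans_p": self.morans_p,
            "frac_threshold": self.frac_threshold,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def write_flags(self, path: str | Path) -> None:
        pd.DataFrame(
            {"spot_id": self.spot_ids, "coloc": self.coloc.astype(int)}
        ).to_csv(path, sep="\t", index=False)


def coloc_flags(
    spot_scores: CellTypeScoreMatrix,
    type_a: str,
    type_b: str,
    frac: float = 0.10,
) -> tuple[np.ndarray, float]:
    """Flag spots where both focal types carry >= frac of the summed scores.

    Spots whose scores sum to zero are never flagged.  Returns the boolean
    flags and their mean (the co-localization rate).
    """
    if type_a == type_b:
        raise ValueError("focal types must differ")
    if not 0 < frac <= 0.5:
        raise ValueError("frac must lie in (0, 0.5]")
    a = spot_scores.column(type_a)
    b = spot_scores.column(type_b)
    total = spot_scores.scores.sum(axis=1)
    with np.errstate(invalid="ignore"):
        flags = (total > 0) & (a >= frac * total) & (b >= frac * total)
    return flags, float(flags.mean())


def coloc_permutation_test(
    spot_scores: CellTypeScoreMatrix,
    type_a: str,
    type_b: str,
    frac: float = 0.10,
    n_perm: int = 1000,
    seed: int = 0,
) -> ColocResult:
    """Permutation test of the co-localization rate.

    Each permutation independently shuffles every cell-type score column
    across spots (sampling without replacement within the column, so each
    column's multiset of scores is preserved exactly) and recomputes the
    rate.  Add-one tail p-values:

    * ``p_upper`` = (1 + #{perm rate >= observed}) / (1 + n_perm) — tests
      excess co-localization;
    * ``p_lower`` analogous with <= — tests deficit (slides can sit below
      the null as well as above it).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    flags, rate = coloc_flags(spot_scores, type_a, type_b, frac)
    rng = np.random.default_rng(seed)
    s = spot_scores.scores
    n_spots, n_types = s.shape
    perm_rates = np.empty(n_perm)
    ja = int(np.where(spot_scores.cell_types == type_a)[0][0])
    jb = int(np.where(spot_scores.cell_types == type_b)[0][0])
    for k in range(n_perm):
        perm = np.empty_like(s)
        for j in range(n_types):
            perm[:, j] = s[rng.permutation(n_spots), j]
        total = perm.sum(axis=1)
        f = (total > 0) & (perm[:, ja] >= frac * total) & (perm[:, jb] >= frac * total)
        perm_rates[k] = f.mean()
    p_upper = (1 + np.sum(perm_rates >= rate)) / (1 + n_perm)
    p_lower = (1 + np.sum(perm_rates <= rate)) / (1 + n_perm)
    return ColocResult(
        coloc=flags,
        rate=rate,
        perm_rates=perm_rates,
        p_upper=float(p_upper),
        p_lower=float(p_lower),
        frac_threshold=frac,
        n_perm=n_perm,
        seed=seed,
        spot_ids=spot_scores.cell_ids,
    )


def hex_neighbor_pairs(array_row: np.ndarray, array_col: np.ndarray) -> np.ndarray:
    """Index pairs (i, j), i < j, of lattice neighbors under the Visium
    offsets (0, +/-2) and (+/-1, +/-1)."""
    coord_index = {
        (int(r), int(c)): i for i, (r, c) in enumerate(zip(array_row, array_col))
    }
    pairs = []
    for i, (r, c) in enumerate(zip(array_row, array_col)):
        for dr, dc in HEX_OFFSETS:
            j = coord_index.get((int(r) + dr, int(c) + dc))
            if j is not None and j > i:
                pairs.append((i, j))
    return np.asarray(pairs, dtype=int).reshape(-1, 2)


def morans_i(
    flags: np.ndarray,
    slide: SpatialSlide,
    n_mc: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Moran's I of binary co-localization flags on the slide's hex lattice.

    I = (N/W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2
    with w_ij = 1 for lattice neighbors, else 0.  The p-value is the upper
    tail of a Monte-Carlo permutation of the flags over spots when the
    observed I exceeds the null expectation -1/(N-1), the lower tail
    otherwise (add-one estimator).  Returns (nan, nan) with a warning when
    the flags are constant (I undefined).
    """
    import warnings

    x = np.asarray(flags, dtype=float)
    n = len(x)
    if n != slide.n_spots:
        raise ValueError("flags length must match number of spots")
    if len(np.unique(x)) < 2:
        warnings.warn("constant flags: Moran's I undefined")
        return float("nan"), float("nan")
    pairs = hex_neighbor_pairs(slide.array_row, slide.array_col)
    if pairs.size == 0:
        raise ValueError("no neighboring spot pairs on the lattice")

    def _moran(v: np.ndarray) -> float:
        z = v - v.mean()
        num = 2.0 * np.sum(z[pairs[:, 0]] * z[pairs[:, 1]])  # symmetric pairs
        w_total = 2.0 * len(pairs)
        return (n / w_total) * num / np.sum(z**2)

    i_obs = _moran(x)
    rng = np.random.default_rng(seed)
    null = np.empty(n_mc)
    for k in range(n_mc):
        null[k] = _moran(rng.permutation(x))
    expectation = -1.0 / (n - 1)
    if i_obs >= expectation:
        p = (1 + np.sum(null >= i_obs)) / (1 + n_mc)
    else:
        p = (1 + np.sum(null <= i_obs)) / (1 + n_mc)
    return float(i_obs), float(p)


def analyze_slide(
    spot_scores: CellTypeScoreMatrix,
    slide: SpatialSlide,
    type_a: str,
    type_b: str,
    frac: float = 0.10,
    n_perm: int = 1000,
    n_mc: int = 999,
    seed: int = 0,
) -> ColocResult:
    """Full spatial analysis: co-localization rate, permutation test, Moran's I."""
    res = coloc_permutation_test(spot_scores, type_a, type_b, frac, n_perm, seed)
    tissue = slide.tissue_subset()
    if not np.array_equal(np.asarray(spot_scores.cell_ids), tissue.spot_ids):
        raise ValueError("spot score IDs must match the slide's in-tissue spots")
    if len(np.unique(res.coloc.astype(int))) >= 2:
        i_val, i_p = morans_i(res.coloc, tissue, n_mc=n_mc, seed=seed)
        res.morans_i, res.morans_p = i_val, i_p
    return res
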