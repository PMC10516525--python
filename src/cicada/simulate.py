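"""Synthetic scRNA-seq, CITE-seq and Visium-style data with planted truth.

The generator emulates the structure the pipeline assumes of its inputs:
marker-separable cell types with negative-binomial counts, heterotypic
doublets that are either plain sums of two singlets (artifactual) or sums
carrying a multiplicative interaction signature on dedicated genes
(biological), antibody counts that are high on a type's own surface markers,
and hexagonal-lattice slides whose spots mix type profiles with an optional
co-enriched hotspot.  Every planted label is recorded so downstream calls
can be scored without re-generation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from cicada.io_formats import AntibodyCaptureMatrix, CellExpressionMatrix, SpatialSlide
from cicada.reference_sets import ReferenceMatrix

NB_DISPERSION = 0.5  # var = mu + phi * mu^2, fixed for all simulated counts


@dataclass
class HotspotSpec:
    """A rectangular array-coordinate region where the two focal types are
    co-enriched by ``enrichment`` on their Dirichlet weights."""

    row_lo: int
    row_hi: int
    col_lo: int
    col_hi: int
    enrichment: float = 12.0

    def contains(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return (
            (row >= self.row_lo)
            & (row <= self.row_hi)
            & (col >= self.col_lo)
            & (col <= self.col_hi)
        )


@dataclass
class SimulationConfig:
    """Knobs for the single-cell and slide generators.

    Defaults give three marker-separable immune-like cell types at realistic
    sparsity (negative binomial, dispersion 0.5, log-normal gene means around
    ``base_rate``), with the first two types focal for doublet injection.
    """

    n_types: int = 3
    cells_per_type: int = 200
    n_genes: int = 1000
    n_markers_per_type: int = 20
    marker_effect: float = 24.0
    base_rate: float = 2.0
    n_bio_doublets: int = 50
    n_art_doublets: int = 50
    n_interaction_genes: int = 20
    interaction_effect: float = 4.0
    interaction_base_rate: float = 16.0
    n_cite_markers_per_type: int = 1
    cite_pos_rate: float = 60.0
    cite_neg_rate: float = 2.0
    slide_rows: int = 30
    slide_cols: int = 60
    spot_depth: float = 3000.0
    immune_fraction: float = 0.15
    immune_frac_conc: float = 300.0
    immune_split_conc: float = 8.0
    hotspot: HotspotSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_types", "cells_per_type", "n_genes", "n_markers_per_type"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_types < 2:
            raise ValueError("need at least 2 cell types")
        for name in ("marker_effect", "interaction_effect"):
            if getattr(self, name) <= 1:
                raise ValueError(f"{name} must exceed 1")
        if self.n_bio_doublets < 0 or self.n_art_doublets < 0:
            raise ValueError("doublet counts must be >= 0")
        if self.n_genes < self.n_types * self.n_markers_per_type + self.n_interaction_genes:
            raise ValueError("n_genes too small for the requested marker/interaction blocks")

    @property
    def type_names(self) -> list[str]:
        return [f"type{chr(ord('A') + i)}" for i in range(self.n_types)]


@dataclass
class SingleCellTruth:
    """Planted labels: per cell its kind, type (or focal pair) and sources."""

    labels: pd.DataFrame  # cell_id, kind, cell_type, source_a, source_b
    interaction_genes: np.ndarray
    marker_genes: dict[str, np.ndarray]
    type_profiles: np.ndarray  # genes x types, expected counts

    def cells_of_kind(self, kind: str) -> np.ndarray:
        t = self.labels
        return t.loc[t["kind"] == kind, "cell_id"].to_numpy(object)


def _nb(rng: np.random.Generator, mean: np.ndarray, size=None) -> np.ndarray:
    """Negative binomial with fixed dispersion; mean can be an array."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    n = 1.0 / NB_DISPERSION
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size if size is not None else mean.shape)


def _type_profiles(cfg: SimulationConfig, rng: np.random.Generator):
    """Expected count per gene per type; markers boosted in their own type."""
    base = rng.lognormal(np.log(cfg.base_rate), 0.4, cfg.n_genes)
    profiles = np.tile(base[:, None], (1, cfg.n_types))
    markers: dict[str, np.ndarray] = {}
    for t, name in enumerate(cfg.type_names):
        lo = t * cfg.n_markers_per_type
        hi = lo + cfg.n_markers_per_type
        profiles[lo:hi, :] = base[lo:hi, None] * 0.05  # markers near-silent off-type
        profiles[lo:hi, t] = base[lo:hi] * cfg.marker_effect
        markers[name] = np.arange(lo, hi)
    # interaction genes emulate inducible immune-response genes (cytokines,
    # MHC): constitutively well-detected in every type, so a doublet's fold
    # change on them is observable after presence filtering
    i_lo = cfg.n_types * cfg.n_markers_per_type
    profiles[i_lo : i_lo + cfg.n_interaction_genes, :] = cfg.interaction_base_rate
    return profiles, markers


def simulate_singlecell(
    cfg: SimulationConfig,
) -> tuple[CellExpressionMatrix, AntibodyCaptureMatrix, SingleCellTruth]:
    """Generate counts, antibody counts and truth labels.

    Layout: ``cells_per_type`` singlets per type, then ``n_art_doublets``
    artifactual doublets (exact sums of a random focal-A and focal-B
    singlet's counts), then ``n_bio_doublets`` biological doublets (the same
    sums with the interaction-gene counts multiplied by
    ``interaction_effect``).  The focal pair is the first two types.  CITE
    counts are negative binomial with ``cite_pos_rate`` on a cell's own
    type markers (both types for doublets) and ``cite_neg_rate`` elsewhere.
    """
    rng = np.random.default_rng(cfg.seed)
    profiles, markers = _type_profiles(cfg, rng)
    gene_ids = np.array([f"gene_{i:04d}" for i in range(cfg.n_genes)], dtype=object)
    interaction = np.arange(
        cfg.n_types * cfg.n_markers_per_type,
        cfg.n_types * cfg.n_markers_per_type + cfg.n_interaction_genes,
    )

    cols: list[np.ndarray] = []
    rows: list[dict] = []
    singlet_ids_by_type: dict[str, list[str]] = {t: [] for t in cfg.type_names}
    for t, name in enumerate(cfg.type_names):
        for c in range(cfg.cells_per_type):
            cid = f"{name}_s{c:04d}"
            cols.append(_nb(rng, profiles[:, t]))
            rows.append(
                {"cell_id": cid, "kind": "singlet", "cell_type": name, "source_a": "", "source_b": ""}
            )
            singlet_ids_by_type[name].append(cid)

    focal_a, focal_b = cfg.type_names[0], cfg.type_names[1]
    id_index = {r["cell_id"]: i for i, r in enumerate(rows)}

    def _doublet(kind: str, j: int) -> None:
        sa = singlet_ids_by_type[focal_a][rng.integers(cfg.cells_per_type)]
        sb = singlet_ids_by_type[focal_b][rng.integers(cfg.cells_per_type)]
        counts = cols[id_index[sa]] + cols[id_index[sb]]
        if kind == "bio_doublet":
            counts = counts.copy()
            counts[interaction] = np.round(counts[interaction] * cfg.interaction_effect).astype(
                counts.dtype
            )
        cols.append(counts)
        rows.append(
            {
                "cell_id": f"{kind}_{j:04d}",
                "kind": kind,
                "cell_type": f"{focal_a}+{focal_b}",
                "source_a": sa,
                "source_b": sb,
            }
        )

    for j in range(cfg.n_art_doublets):
        _doublet("art_doublet", j)
    for j in range(cfg.n_bio_doublets):
        _doublet("bio_doublet", j)

    labels = pd.DataFrame(rows)
    counts = sp.csc_matrix(np.column_stack(cols))
    expr = CellExpressionMatrix(counts, gene_ids, labels["cell_id"].to_numpy(object))

    # CITE counts: one (or more) surface markers per type
    cite_ids = []
    cite_of_type: dict[str, list[str]] = {}
    for name in cfg.type_names:
        for k in range(cfg.n_cite_markers_per_type):
            mid = f"AB_{name}_{k}"
            cite_ids.append(mid)
            cite_of_type.setdefault(name, []).append(mid)
    cite_rows = []
    for mid in cite_ids:
        owner = mid.split("_")[1]
        means = np.empty(expr.n_cells)
        for i, r in enumerate(rows):
            positive = owner in r["cell_type"].split("+")
            means[i] = cfg.cite_pos_rate if positive else cfg.cite_neg_rate
        cite_rows.append(_nb(rng, means))
    cite = AntibodyCaptureMatrix(
        sp.csc_matrix(np.vstack(cite_rows)),
        np.array(cite_ids, dtype=object),
        expr.cell_ids,
    )

    truth = SingleCellTruth(
        labels=labels,
        interaction_genes=gene_ids[interaction],
        marker_genes={t: gene_ids[idx] for t, idx in markers.items()},
        type_profiles=profiles,
    )
    return expr, cite, truth


def reference_from_simulation(
    cfg: SimulationConfig, n_samples_per_type: int = 3, depth: float = 1e5, seed: int | None = None
) -> ReferenceMatrix:
    """Bulk-style labeled reference drawn from the same type profiles, for
    building weighted gene sets end-to-end."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    profiles, _ = _type_profiles(cfg, np.random.default_rng(cfg.seed))
    gene_ids = np.array([f"gene_{i:04d}" for i in range(cfg.n_genes)], dtype=object)
    cols, labels = [], []
    for t, name in enumerate(cfg.type_names):
        scale = depth / profiles[:, t].sum()
        for _ in range(n_samples_per_type):
            cols.append(_nb(rng, profiles[:, t] * scale))
            labels.append(name)
    return ReferenceMatrix(
        np.column_stack(cols).astype(float), gene_ids, np.array(labels, dtype=object)
    )


@dataclass
class SlideTruth:
    """Per-spot planted composition over cell types, plus the hotspot mask."""

    composition: pd.DataFrame  # spot_id x type proportions
    in_hotspot: np.ndarray


def hex_lattice(n_rows: int, n_cols: int) -> tuple[np.ndarray, np.ndarray]:
    """Visium-style array coordinates: all (row, col) with row+col even."""
    rows, cols = [], []
    for r in range(n_rows):
        for c in range(n_cols):
            if (r + c) % 2 == 0:
                rows.append(r)
                cols.append(c)
    return np.asarray(rows), np.asarray(cols)


def simulate_slide(cfg: SimulationConfig) -> tuple[SpatialSlide, SlideTruth]:
    """Hex-lattice slide whose spot counts mix the type profiles.

    Each spot carries an immune compartment of expected fraction
    ``immune_fraction`` (a Beta draw at concentration ``immune_frac_conc``)
    split between the two focal types by a Beta(``immune_split_conc``) draw;
    the remaining mass is divided among the other types by a flat Dirichlet.
    Inside the hotspot the immune fraction's odds are multiplied by
    ``hotspot.enrichment``, co-enriching the focal pair — the signature of a
    region of joint infiltration.  Spot counts are negative binomial around
    ``spot_depth`` expected total counts.
    """
    rng = np.random.default_rng(cfg.seed)
    profiles, _ = _type_profiles(cfg, np.random.default_rng(cfg.seed))
    gene_ids = np.array([f"gene_{i:04d}" for i in range(cfg.n_genes)], dtype=object)
    row, col = hex_lattice(cfg.slide_rows, cfg.slide_cols)
    n_spots = len(row)
    in_hot = (
        cfg.hotspot.contains(row, col) if cfg.hotspot is not None else np.zeros(n_spots, bool)
    )

    f0 = cfg.immune_fraction
    odds = f0 / (1 - f0)
    f_hot = 1.0 if cfg.hotspot is None else (
        cfg.hotspot.enrichment * odds / (1 + cfg.hotspot.enrichment * odds)
    )
    comp = np.empty((n_spots, cfg.n_types))
    k = cfg.immune_frac_conc
    for i in range(n_spots):
        mean_f = f_hot if in_hot[i] else f0
        f = rng.beta(k * mean_f, k * (1 - mean_f))
        u = rng.beta(cfg.immune_split_conc, cfg.immune_split_conc)
        rest = rng.dirichlet(np.ones(cfg.n_types - 2)) if cfg.n_types > 2 else np.array([])
        comp[i, 0] = f * u
        comp[i, 1] = f * (1 - u)
        if cfg.n_types > 2:
            comp[i, 2:] = (1 - f) * rest

    # expected gene profile per spot = composition-weighted mixture, scaled to depth
    per_type = profiles / profiles.sum(axis=0, keepdims=True)  # gene distribution per type
    spot_mean = comp @ per_type.T * cfg.spot_depth
    counts = _nb(rng, spot_mean)

    spot_ids = np.array([f"spot_{r:03d}_{c:03d}" for r, c in zip(row, col)], dtype=object)
    slide = SpatialSlide(
        counts=sp.csr_matrix(counts),
        spot_ids=spot_ids,
        gene_ids=gene_ids,
        array_row=row,
        array_col=col,
        in_tissue=np.ones(n_spots, bool),
    )
    truth = SlideTruth(
        composition=pd.DataFrame(comp, index=spot_ids, columns=cfg.type_names),
        in_hotspot=in_hot,
    )
    return slide, truth


def simulate_null_scores(
    n_spots: int, cell_types: list[str], seed: int = 0
) -> np.ndarray:
    """iid Uniform(0, 1) spot x type scores — a no-structure null slide for
    calibration of the co-localization permutation test."""
    rng = np.random.default_rng(seed)
    return rng.uniform(0, 1, size=(n_spots, len(cell_types)))
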