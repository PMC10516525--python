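"""Readers, writers and QC for single-cell and Visium-style spatial data.

Counts are carried as scipy CSC sparse matrices with explicit gene/cell ID
lists.  Matrix Market files are 1-based on disk (the format's convention);
every index exposed here is 0-based.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

DEFAULT_MITO_PATTERN = r"(?i)^MT-"
DEFAULT_RIBO_PATTERN = r"(?i)^RP[SL]"


class FormatError(ValueError):
    """A file does not conform to the expected on-disk dialect."""


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(np.unique(ids)) != len(ids):
        raise ValueError(f"duplicate {what} ids")


@dataclass
class CellExpressionMatrix:
    """Raw integer counts, genes x cells.

    The universal expression carrier: QC, scoring and synthetic-doublet
    construction all consume and produce this type.  ``sample_of_origin``
    optionally tags each cell with its sample (e.g. "WT" / "IL21").
    """

    counts: sp.csc_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    sample_of_origin: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")
        data = self.counts.data
        if data.size and not np.allclose(data, np.round(data)):
            raise FormatError("expression counts must be integers")
        if self.sample_of_origin is not None:
            self.sample_of_origin = np.asarray(self.sample_of_origin, dtype=object)
            if len(self.sample_of_origin) != len(self.cell_ids):
                raise ValueError("sample_of_origin length mismatch")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset(
        self, gene_mask: np.ndarray | None = None, cell_mask: np.ndarray | None = None
    ) -> "CellExpressionMatrix":
        """Return a sub-matrix; masks may be boolean or integer indexers."""
        gi = np.arange(self.n_genes) if gene_mask is None else np.arange(self.n_genes)[gene_mask] if np.asarray(gene_mask).dtype == bool else np.asarray(gene_mask)
        ci = np.arange(self.n_cells) if cell_mask is None else np.arange(self.n_cells)[cell_mask] if np.asarray(cell_mask).dtype == bool else np.asarray(cell_mask)
        return CellExpressionMatrix(
            counts=self.counts[gi][:, ci],
            gene_ids=self.gene_ids[gi],
            cell_ids=self.cell_ids[ci],
            sample_of_origin=None if self.sample_of_origin is None else self.sample_of_origin[ci],
        )


@dataclass
class AntibodyCaptureMatrix:
    """CITE-seq antibody counts, markers x cells, cell order shared with RNA."""

    counts: sp.csc_matrix
    marker_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.shape != (len(self.marker_ids), len(self.cell_ids)):
            raise ValueError("antibody counts shape mismatch")
        _check_unique(self.marker_ids, "marker")
        _check_unique(self.cell_ids, "cell")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative antibody counts")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


@dataclass
class SpatialSlide:
    """Visium-style slide: spot x gene counts plus hexagonal array coordinates.

    Spots sit on the 10x hex lattice indexed by (array_row, array_col) with
    parity offset: a spot's six neighbours are at offsets (0, +/-2) and
    (+/-1, +/-1).  Only ``in_tissue`` spots enter analysis.
    """

    counts: sp.csr_matrix  # spots x genes
    spot_ids: np.ndarray
    gene_ids: np.ndarray
    array_row: np.ndarray
    array_col: np.ndarray
    in_tissue: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.array_row = np.asarray(self.array_row, dtype=int)
        self.array_col = np.asarray(self.array_col, dtype=int)
        if self.in_tissue is None:
            self.in_tissue = np.ones(len(self.spot_ids), dtype=bool)
        self.in_tissue = np.asarray(self.in_tissue, dtype=bool)
        n = len(self.spot_ids)
        if self.counts.shape[0] != n or self.counts.shape[1] != len(self.gene_ids):
            raise ValueError("slide counts shape mismatch")
        for arr, what in ((self.array_row, "array_row"), (self.array_col, "array_col"), (self.in_tissue, "in_tissue")):
            if len(arr) != n:
                raise ValueError(f"{what} length mismatch")
        coords = set(zip(self.array_row.tolist(), self.array_col.tolist()))
        if len(coords) != n:
            raise ValueError("duplicate (array_row, array_col) pairs")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    def tissue_subset(self) -> "SpatialSlide":
        """Restrict to in-tissue spots."""
        m = self.in_tissue
        return SpatialSlide(
            counts=self.counts[m],
            spot_ids=self.spot_ids[m],
            gene_ids=self.gene_ids,
            array_row=self.array_row[m],
            array_col=self.array_col[m],
            in_tissue=self.in_tissue[m],
        )


@dataclass
class QCParams:
    """Cell/gene quality-control thresholds.

    Defaults: genes kept if present in >= 10 cells, cells kept if >= 100
    genes detected and mitochondrial fraction <= 5% (10% is appropriate for
    datasets sensitive to the mitochondrial filter).
    """

    min_cells_per_gene: int = 10
    min_genes_per_cell: int = 100
    max_mito_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.min_cells_per_gene < 0 or self.min_genes_per_cell < 0:
            raise ValueError("QC thresholds must be >= 0")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# readers / writers


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _find_member(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FormatError(f"missing file member: {stem}[.gz] in {directory}")


def read_10x_counts(
    path: str | Path,
) -> tuple[CellExpressionMatrix, AntibodyCaptureMatrix | None]:
    """Read a 10x feature-barcode matrix (MTX triplet directory or HDF5 file).

    Features typed "Antibody Capture" are split out into an
    :class:`AntibodyCaptureMatrix`; everything else ("Gene Expression", or
    untyped 2-column features files) goes to the expression matrix.  Row
    order within each modality is preserved from the file.
    """
    path = Path(path)
    if path.is_dir():
        genes, feature_types, barcodes, mat = _read_mtx_dir(path)
    elif path.suffix in {".h5", ".hdf5"}:
        genes, feature_types, barcodes, mat = _read_10x_h5(path)
    else:
        raise FormatError(f"not a triplet directory or HDF5 file: {path}")

    is_ab = feature_types == "Antibody Capture"
    expr = CellExpressionMatrix(
        counts=mat[~is_ab], gene_ids=genes[~is_ab], cell_ids=barcodes
    )
    antibody = None
    if is_ab.any():
        antibody = AntibodyCaptureMatrix(
            counts=mat[is_ab], marker_ids=genes[is_ab], cell_ids=barcodes
        )
    return expr, antibody


def _read_mtx_dir(directory: Path):
    mtx = _find_member(directory, "matrix.mtx")
    try:
        feat = _find_member(directory, "features.tsv")
    except FormatError:
        feat = _find_member(directory, "genes.tsv")
    bc = _find_member(directory, "barcodes.tsv")

    with _open_maybe_gz(mtx) as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.csr_matrix(mat)
    if not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError(f"non-integer expression values in {mtx}")

    features = pd.read_csv(feat, sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(bc, sep="\t", header=None, dtype=str)[0].to_numpy(dtype=object)
    # features.tsv: id, name[, feature_type]; use the name column when present
    name_col = 1 if features.shape[1] > 1 else 0
    genes = features[name_col].to_numpy(dtype=object)
    if features.shape[1] > 2:
        ftypes = features[2].to_numpy(dtype=object)
    else:
        ftypes = np.full(len(genes), "Gene Expression", dtype=object)
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix {mat.shape} does not match {len(genes)} features x {len(barcodes)} barcodes"
        )
    return genes, np.asarray(ftypes), barcodes, mat


def _read_10x_h5(path: Path):
    import h5py

    with h5py.File(path, "r") as f:
        if "matrix" not in f:
            raise FormatError(f"no 'matrix' group in {path}")
        g = f["matrix"]
        data = g["data"][:]
        mat = sp.csc_matrix(
            (data, g["indices"][:], g["indptr"][:]), shape=tuple(g["shape"][:])
        )
        genes = g["features/name"][:].astype(str).astype(object)
        ftypes = g["features/feature_type"][:].astype(str).astype(object)
        barcodes = g["barcodes"][:].astype(str).astype(object)
    if not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError(f"non-integer expression values in {path}")
    return genes, np.asarray(ftypes), barcodes, sp.csr_matrix(mat)


def write_10x_counts(m: CellExpressionMatrix, directory: str | Path) -> None:
    """Write an MTX triplet (matrix.mtx, features.tsv, barcodes.tsv)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sp.coo_matrix(m.counts.astype(int)))
    feats = pd.DataFrame(
        {"id": m.gene_ids, "name": m.gene_ids, "type": "Gene Expression"}
    )
    feats.to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(m.cell_ids).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_dense_tsv(path: str | Path) -> CellExpressionMatrix:
    """Read a dense genes-in-rows TSV with a header row of cell IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CellExpressionMatrix(
        counts=sp.csc_matrix(df.to_numpy()),
        gene_ids=df.index.to_numpy(dtype=object),
        cell_ids=df.columns.to_numpy(dtype=object),
    )


def read_visium(
    counts_dir: str | Path, positions_path: str | Path
) -> SpatialSlide:
    """Assemble a slide from a counts triplet plus a tissue_positions table.

    The positions file is the Space Ranger ``tissue_positions_list.csv``
    dialect: barcode, in_tissue, array_row, array_col, pixel row, pixel col
    (header optional).
    """
    expr, _ = read_10x_counts(counts_dir)
    first = pd.read_csv(positions_path, nrows=1, header=None)
    has_header = str(first.iloc[0, 0]).lower() in {"barcode", "barcodes"}
    pos = pd.read_csv(
        positions_path,
        header=0 if has_header else None,
        names=["barcode", "in_tissue", "array_row", "array_col", "pxl_row", "pxl_col"],
    )
    pos = pos.set_index("barcode").loc[expr.cell_ids]
    return SpatialSlide(
        counts=expr.counts.T.tocsr(),
        spot_ids=expr.cell_ids,
        gene_ids=expr.gene_ids,
        array_row=pos["array_row"].to_numpy(),
        array_col=pos["array_col"].to_numpy(),
        in_tissue=pos["in_tissue"].to_numpy().astype(bool),
    )


# ---------------------------------------------------------------------------
# QC and normalization


def mito_fraction(m: CellExpressionMatrix, mito_pattern: str = DEFAULT_MITO_PATTERN) -> np.ndarray:
    """Per-cell fraction of counts on mitochondrial genes (0 where the cell is empty)."""
    rx = re.compile(mito_pattern)
    is_mito = np.fromiter((bool(rx.search(str(g))) for g in m.gene_ids), bool, m.n_genes)
    totals = np.asarray(m.counts.sum(axis=0)).ravel()
    mito = np.asarray(m.counts[is_mito].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / np.maximum(totals, 1e-300), 0.0)
    return frac


def apply_qc(
    m: CellExpressionMatrix,
    q: QCParams | None = None,
    mito_pattern: str = DEFAULT_MITO_PATTERN,
) -> CellExpressionMatrix:
    """Filter cells and genes, in the fixed order mito -> gene -> cell.

    1. drop cells whose mitochondrial count fraction exceeds
       ``max_mito_fraction``;
    2. drop genes detected in fewer than ``min_cells_per_gene`` of the
       remaining cells;
    3. drop cells with fewer than ``min_genes_per_cell`` detected genes.

    Ties keep their input order.  Raises if no cell survives.
    """
    q = q or QCParams()
    keep_cells = mito_fraction(m, mito_pattern) <= q.max_mito_fraction
    m = m.subset(cell_mask=keep_cells)
    detected = m.counts > 0
    keep_genes = np.asarray(detected.sum(axis=1)).ravel() >= q.min_cells_per_gene
    m = m.subset(gene_mask=keep_genes)
    keep_cells2 = np.asarray((m.counts > 0).sum(axis=0)).ravel() >= q.min_genes_per_cell
    m = m.subset(cell_mask=keep_cells2)
    if m.n_cells == 0:
        raise ValueError("empty after QC: no cell passed the filters")
    return m


def qc_report(
    m: CellExpressionMatrix,
    q: QCParams | None = None,
    mito_pattern: str = DEFAULT_MITO_PATTERN,
) -> pd.DataFrame:
    """Per-cell QC table (cell_id, n_genes, total_counts, mito_fraction, kept)."""
    q = q or QCParams()
    kept = apply_qc(m, q, mito_pattern)
    kept_ids = set(kept.cell_ids.tolist())
    return pd.DataFrame(
        {
            "cell_id": m.cell_ids,
            "n_genes": np.asarray((m.counts > 0).sum(axis=0)).ravel(),
            "total_counts": np.asarray(m.counts.sum(axis=0)).ravel(),
            "mito_fraction": mito_fraction(m, mito_pattern),
            "kept": [c in kept_ids for c in m.cell_ids],
        }
    )


def lognormalize(
    counts: sp.spmatrix | np.ndarray,
    scale_factor: float = 10_000.0,
    cell_axis: int = 1,
    zscale: bool = False,
) -> np.ndarray:
    """Depth-normalize and log-transform: ln(1 + count / cell_total * scale_factor).

    ``cell_axis`` selects which axis indexes cells (1 for genes x cells, 0
    for spots x genes).  With ``zscale`` the output is additionally centred
    and scaled per gene (unit variance, zero mean) — the representation fed
    to PCA/clustering, not to set scoring.
    """
    x = np.asarray(counts.todense() if sp.issparse(counts) else counts, dtype=float)
    totals = x.sum(axis=0 if cell_axis == 1 else 1)
    if np.any(totals == 0):
        bad = np.where(totals == 0)[0]
        raise ValueError(f"cell(s) with zero total counts at position(s) {bad.tolist()}")
    if cell_axis == 1:
        out = np.log1p(x / totals[None, :] * scale_factor)
    else:
        out = np.log1p(x / totals[:, None] * scale_factor)
    if zscale:
        gene_axis = 1 - cell_axis
        mean = out.mean(axis=cell_axis, keepdims=True)
        sd = out.std(axis=cell_axis, keepdims=True)
        sd[sd == 0] = 1.0
        out = (out - mean) / sd
        del gene_axis
    return out


def clr_normalize(a: AntibodyCaptureMatrix) -> np.ndarray:
    """Centered log-ratio transform per cell across markers.

    clr(x_j) = ln(1+x_j) - mean_k ln(1+x_k); rows (markers) x cells, dense.
    """
    x = np.log1p(np.asarray(a.counts.todense(), dtype=float))
    return x - x.mean(axis=0, keepdims=True)
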