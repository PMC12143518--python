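"""Count-matrix I/O, quality control and log-normalization.

Counts are stored gene x cell (transcripts in rows, barcodes in
columns).  QC follows the standard droplet workflow: cells are removed
when their number of detected genes falls outside [200, 3000] or their
mitochondrial count fraction exceeds 5%, then genes detected in fewer
than 20 cells are dropped.  Boundary cells (exactly 200 or 3000 genes)
and genes detected in exactly 20 cells are retained.  Normalization is
library-size scaling to a common total followed by ln(1 + x), with a
plain ln(1 + x) variant available.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "EmptyResultError",
    "NormalizedMatrix",
    "ParseError",
    "QCMetrics",
    "QCThresholds",
    "RawCountMatrix",
    "compute_qc_metrics",
    "filter_cells",
    "filter_genes",
    "log_normalize",
    "read_counts",
    "write_counts",
]

MITO_PREFIXES = ("MT-", "mt-", "Mt-")


class ParseError(ValueError):
    """Malformed or inconsistent input file."""


class EmptyResultError(ValueError):
    """A filter removed every cell or every gene."""


def _default_mito_mask(gene_ids: np.ndarray) -> np.ndarray:
    return np.array([g.startswith(MITO_PREFIXES) for g in gene_ids], dtype=bool)


@dataclass
class RawCountMatrix:
    """Gene x cell non-negative integer counts with identifiers.

    ``mito_mask`` marks mitochondrial genes; by default genes whose
    symbol starts with ``MT-``/``mt-``.
    """

    counts: sp.csr_matrix = field(repr=False)
    gene_ids: np.ndarray
    barcodes: np.ndarray
    mito_mask: np.ndarray | None = None

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        n, p = self.counts.shape
        if len(self.gene_ids) != n:
            raise ParseError(f"{len(self.gene_ids)} gene ids for {n} matrix rows")
        if len(self.barcodes) != p:
            raise ParseError(f"{len(self.barcodes)} barcodes for {p} matrix columns")
        if len(set(self.gene_ids)) != n:
            raise ParseError("gene identifiers are not unique")
        if len(set(self.barcodes)) != p:
            raise ParseError("cell barcodes are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            bad = np.argwhere(self.counts.toarray() < 0)[0] if n * p < 1e6 else None
            raise ParseError(f"negative count entry{'' if bad is None else f' at {tuple(bad)}'}")
        if self.counts.nnz and np.any(self.counts.data != np.round(self.counts.data)):
            raise ParseError("non-integer count entries")
        if self.mito_mask is None:
            self.mito_mask = _default_mito_mask(self.gene_ids)
        self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
        if len(self.mito_mask) != n:
            raise ParseError("mito mask length does not match gene count")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class QCThresholds:
    """Cell/gene retention thresholds (strict-inequality removal)."""

    min_genes_per_cell: int = 200
    max_genes_per_cell: int = 3000
    min_cells_per_gene: int = 20
    max_mito_fraction: float = 0.05

    def __post_init__(self):
        if not self.min_genes_per_cell < self.max_genes_per_cell:
            raise ValueError("min_genes_per_cell must be below max_genes_per_cell")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class QCMetrics:
    """Per-cell QC metrics: count depth, detected genes, mito fraction."""

    count_depth: np.ndarray
    n_genes: np.ndarray
    mito_fraction: np.ndarray

    def to_frame(self, barcodes=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "count_depth": self.count_depth,
                "n_genes": self.n_genes,
                "mito_fraction": self.mito_fraction,
            }
        )
        if barcodes is not None:
            df.insert(0, "barcode", np.asarray(barcodes, dtype=object))
        return df


@dataclass(frozen=True)
class NormalizedMatrix:
    """Dense normalized expression, gene x cell, with identifiers."""

    values: np.ndarray = field(repr=False)
    gene_ids: np.ndarray
    barcodes: np.ndarray


def _open_maybe_gz(path, mode="rt"):
    return gzip.open(path, mode) if str(path).endswith(".gz") else open(path, mode)


def _find_triplet_file(d, stems):
    for stem in stems:
        for suffix in ("", ".gz"):
            p = os.path.join(d, stem + suffix)
            if os.path.exists(p):
                return p
    raise ParseError(f"none of {stems} found in {d}")


def read_counts(path, format: str = "10x-mtx") -> RawCountMatrix:
    """Read a gene x cell count matrix.

    ``10x-mtx`` expects a directory with ``matrix.mtx``,
    ``features.tsv``/``genes.tsv`` and ``barcodes.tsv`` (gzipped
    accepted).  ``csv``/``tsv`` expect a dense table with gene ids in
    the first column and barcodes in the header.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "10x-mtx":
        mtx = _find_triplet_file(path, ["matrix.mtx"])
        feat = _find_triplet_file(path, ["features.tsv", "genes.tsv"])
        bc = _find_triplet_file(path, ["barcodes.tsv"])
        with _open_maybe_gz(mtx, "rb") as fh:
            try:
                counts = sp.csr_matrix(scipy.io.mmread(fh))
            except Exception as e:  # noqa: BLE001 - surface the offending file
                raise ParseError(f"malformed Matrix Market file {mtx}: {e}") from e
        features = pd.read_csv(feat, sep="\t", header=None, dtype=str)
        barcodes = pd.read_csv(bc, sep="\t", header=None, dtype=str)[0].to_numpy()
        if len(features) != counts.shape[0]:
            raise ParseError(
                f"{feat} lists {len(features)} features but matrix has "
                f"{counts.shape[0]} rows"
            )
        if len(barcodes) != counts.shape[1]:
            raise ParseError(
                f"{bc} lists {len(barcodes)} barcodes but matrix has "
                f"{counts.shape[1]} columns"
            )
        # 10x features.tsv: column 0 = id, column 1 = symbol (if present)
        symbols = features[1] if features.shape[1] > 1 else features[0]
        gene_ids = features[0].to_numpy()
        mito = np.array([s.startswith(MITO_PREFIXES) for s in symbols], dtype=bool)
        return RawCountMatrix(counts, gene_ids, barcodes, mito_mask=mito)
    if format in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if format == "csv" else "\t", index_col=0)
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ParseError(f"{path}: non-numeric entries")
        return RawCountMatrix(
            sp.csr_matrix(vals), df.index.to_numpy(dtype=object),
            df.columns.to_numpy(dtype=object),
        )
    raise ValueError(f"unknown format {format!r}")


def write_counts(X: RawCountMatrix, outdir, format: str = "10x-mtx") -> None:
    """Write a count matrix as a 10x-style triplet or a dense CSV/TSV."""
    os.makedirs(outdir, exist_ok=True)
    if format == "10x-mtx":
        scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), sp.coo_matrix(X.counts))
        pd.DataFrame({0: X.gene_ids, 1: X.gene_ids, 2: "Gene Expression"}).to_csv(
            os.path.join(outdir, "features.tsv"), sep="\t", header=False, index=False
        )
        pd.DataFrame({0: X.barcodes}).to_csv(
            os.path.join(outdir, "barcodes.tsv"), sep="\t", header=False, index=False
        )
    elif format in ("csv", "tsv"):
        pd.DataFrame(
            X.counts.toarray(), index=X.gene_ids, columns=X.barcodes
        ).to_csv(os.path.join(outdir, f"counts.{format}"),
                 sep="," if format == "csv" else "\t")
    else:
        raise ValueError(f"unknown format {format!r}")


def compute_qc_metrics(X: RawCountMatrix) -> QCMetrics:
    """Per-cell count depth, detected genes and mitochondrial fraction.

    A zero-depth cell gets mito_fraction 0 (it fails the minimum-genes
    filter regardless).
    """
    counts = X.counts
    depth = np.asarray(counts.sum(axis=0)).ravel()
    n_genes = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito = np.asarray(counts[X.mito_mask].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(depth > 0, mito / np.maximum(depth, 1), 0.0)
    return QCMetrics(depth.astype(float), n_genes.astype(int), mito_frac)


def filter_cells(
    X: RawCountMatrix, m: QCMetrics, t: QCThresholds = QCThresholds()
) -> tuple[RawCountMatrix, pd.DataFrame]:
    """Remove cells violating the gene-count bounds or the mito cap.

    Keeps cells with ``min_genes <= n_genes <= max_genes`` and
    ``mito_fraction <= max_mito_fraction`` (boundaries retained).
    Returns the filtered matrix and a removal log with one row per cell
    (columns: barcode, kept, reason).
    """
    low = m.n_genes < t.min_genes_per_cell
    high = m.n_genes > t.max_genes_per_cell
    mito = m.mito_fraction > t.max_mito_fraction
    keep = ~(low | high | mito)
    why = [(low, "n_genes below minimum"), (high, "n_genes above maximum"),
           (mito, "mito fraction above maximum")]
    reasons = ["; ".join(w for mask, w in why if mask[i]) for i in range(X.n_cells)]
    log = pd.DataFrame({"barcode": X.barcodes, "kept": keep, "reason": reasons})
    if not keep.any():
        raise EmptyResultError("cell QC removed every cell")
    out = RawCountMatrix(
        X.counts[:, keep], X.gene_ids, X.barcodes[keep], mito_mask=X.mito_mask
    )
    return out, log


def filter_genes(
    X: RawCountMatrix, t: QCThresholds = QCThresholds()
) -> RawCountMatrix:
    """Keep genes detected (count > 0) in at least ``min_cells_per_gene`` cells."""
    detected_in = np.asarray((X.counts > 0).sum(axis=1)).ravel()
    keep = detected_in >= t.min_cells_per_gene
    if not keep.any():
        raise EmptyResultError("gene QC removed every gene")
    return RawCountMatrix(
        X.counts[keep], X.gene_ids[keep], X.barcodes, mito_mask=X.mito_mask[keep]
    )


def log_normalize(
    X: RawCountMatrix,
    scale_factor: float = 1e4,
    method: str = "library-size",
) -> NormalizedMatrix:
    """Log-normalize QC'd counts.

    ``library-size``: x -> ln(1 + scale_factor * x / depth) per cell;
    ``plain-log1p``:  x -> ln(1 + x).  Zeros stay zero under both.
    """
    dense = X.counts.toarray().astype(float)
    if method == "library-size":
        depth = dense.sum(axis=0)
        if np.any(depth == 0):
            bad = X.barcodes[depth == 0][:3]
            raise ValueError(
                f"zero-depth cells (e.g. {list(bad)}); run cell QC before normalizing"
            )
        vals = np.log1p(scale_factor * dense / depth)
    elif method == "plain-log1p":
        vals = np.log1p(dense)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return NormalizedMatrix(vals, X.gene_ids.copy(), X.barcodes.copy())
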