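"""Reading, writing and subsetting UMI count matrices.

The central container is :class:`CountMatrix`: an integer cells-by-genes
matrix of UMI counts together with per-cell sequencing depths ``s_i``.
Depths default to the row sums of the *full* (pre-filtering) gene set,
because the measurement model treats ``s_i`` as the cell's total molecule
count; gene filtering afterwards must not change them.

Supported on-disk formats are a 10x-style Matrix Market triplet directory
(``matrix.mtx`` plus ``genes.tsv`` and ``barcodes.tsv``) and a dense TSV/CSV
table with a header row of gene ids and an index column of cell ids.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "CountFormatError",
    "read_counts",
    "write_counts",
    "top_expressed_genes",
]


class CountFormatError(ValueError):
    """Raised when an input file does not contain a valid UMI count matrix."""


@dataclass
class CountMatrix:
    """UMI counts for ``n`` cells by ``p`` genes with sequencing depths.

    Parameters
    ----------
    counts
        Non-negative integer matrix of shape ``(n_cells, n_genes)``.
    gene_ids, cell_ids
        Unique identifiers for columns and rows respectively.
    depths
        Per-cell sequencing depth ``s_i``.  If omitted, computed as the row
        sums of ``counts`` — i.e. total UMIs over the gene set present at
        construction time.
    metadata
        Free-form provenance (seeds, target depths of null resampling, ...).
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    depths: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise CountFormatError("counts must be a 2-D matrix")
        if self.counts.size == 0:
            raise CountFormatError("empty count matrix")
        if np.any(self.counts < 0):
            raise CountFormatError("negative entries in count matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded, atol=1e-8):
                raise CountFormatError("non-integer entries in count matrix")
            self.counts = rounded.astype(np.int64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n, p = self.counts.shape
        if len(self.gene_ids) != p:
            raise CountFormatError(
                f"{len(self.gene_ids)} gene ids for {p} matrix columns"
            )
        if len(self.cell_ids) != n:
            raise CountFormatError(
                f"{len(self.cell_ids)} cell ids for {n} matrix rows"
            )
        if len(set(self.gene_ids)) != p:
            raise CountFormatError("duplicate gene ids")
        if len(set(self.cell_ids)) != n:
            raise CountFormatError("duplicate cell ids")
        if self.depths is None:
            self.depths = self.counts.sum(axis=1).astype(np.int64)
        else:
            self.depths = np.asarray(self.depths)
            if self.depths.shape != (n,):
                raise CountFormatError("depths length does not match cell count")
        if np.any(self.depths <= 0):
            raise CountFormatError(
                "non-positive sequencing depth; drop empty cells first"
            )

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def zero_genes(self) -> np.ndarray:
        """Boolean mask of genes with zero counts in every cell."""
        return ~self.counts.any(axis=0)

    def subset_genes(self, idx: np.ndarray) -> "CountMatrix":
        """Return a gene subset; depths are carried over unchanged."""
        idx = np.asarray(idx)
        return CountMatrix(
            counts=self.counts[:, idx],
            gene_ids=[self.gene_ids[i] for i in np.atleast_1d(idx)],
            cell_ids=list(self.cell_ids),
            depths=self.depths.copy(),
            metadata=dict(self.metadata),
        )

    def subset_cells(self, idx: np.ndarray) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            counts=self.counts[idx, :],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in np.atleast_1d(idx)],
            depths=self.depths[idx],
            metadata=dict(self.metadata),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            np.array_equal(self.counts, other.counts)
            and self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and np.array_equal(self.depths, other.depths)
        )


def read_counts(
    path: str | Path,
    format: str = "mtx-dir",
    *,
    orientation: str = "genes-by-cells",
    depths: np.ndarray | None = None,
) -> CountMatrix:
    """Load a UMI count matrix from disk.

    Parameters
    ----------
    path
        Directory (``mtx-dir``) or file (``tsv``).
    format
        ``"mtx-dir"``: Matrix Market triplet with ``genes.tsv`` /
        ``barcodes.tsv`` annotations (10x convention).  ``"tsv"``: dense
        table, header row = gene ids, first column = cell ids.
    orientation
        Orientation of the stored matrix for ``mtx-dir``; the 10x default
        is genes-by-cells.  Ignored for ``tsv`` (always cells-by-genes).
    depths
        User-supplied sequencing depths overriding the row sums, e.g. when
        the file holds an already-filtered gene subset.
    """
    path = Path(path)
    if format == "mtx-dir":
        mtx = path / "matrix.mtx"
        genes_f = path / "genes.tsv"
        cells_f = path / "barcodes.tsv"
        for f in (mtx, genes_f, cells_f):
            if not f.exists():
                raise CountFormatError(f"missing file: {f}")
        mat = scipy.io.mmread(mtx)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        gene_ids = genes_f.read_text().split()
        cell_ids = cells_f.read_text().split()
        if orientation == "genes-by-cells":
            mat = mat.T
        elif orientation != "cells-by-genes":
            raise ValueError(f"unknown orientation: {orientation!r}")
        if mat.shape != (len(cell_ids), len(gene_ids)):
            raise CountFormatError(
                f"matrix shape {mat.shape} does not match "
                f"{len(cell_ids)} cells x {len(gene_ids)} genes"
            )
        if depths is None and (path / "depths.tsv").exists():
            depths = read_depths(path / "depths.tsv")
    elif format == "tsv":
        import csv

        try:
            df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        except (pd.errors.EmptyDataError, pd.errors.ParserError, csv.Error) as e:
            raise CountFormatError(f"unreadable table: {path}") from e
        if df.size == 0:
            raise CountFormatError(f"empty table: {path}")
        mat = df.to_numpy()
        gene_ids = [str(c) for c in df.columns]
        cell_ids = [str(i) for i in df.index]
    else:
        raise ValueError(f"unknown format: {format!r}")

    cm = CountMatrix(counts=mat, gene_ids=gene_ids, cell_ids=cell_ids, depths=depths)
    n_zero = int(cm.zero_genes().sum())
    if n_zero:
        logger.warning("%d gene(s) have zero counts in every cell", n_zero)
    return cm


def write_counts(cm: CountMatrix, path: str | Path, format: str = "mtx-dir") -> None:
    """Serialize a :class:`CountMatrix` losslessly.

    ``read_counts(write_counts(cm))`` returns an equal matrix for both
    formats.  Matrix Market output uses the genes-by-cells orientation.
    """
    path = Path(path)
    if format == "mtx-dir":
        path.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.csr_matrix(cm.counts.T)
        scipy.io.mmwrite(path / "matrix.mtx", sparse, field="integer")
        (path / "genes.tsv").write_text("\n".join(cm.gene_ids) + "\n")
        (path / "barcodes.tsv").write_text("\n".join(cm.cell_ids) + "\n")
        np.savetxt(path / "depths.tsv", cm.depths, fmt="%d")
    elif format == "tsv":
        df = pd.DataFrame(cm.counts, index=cm.cell_ids, columns=cm.gene_ids)
        df.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format: {format!r}")


def read_depths(path: str | Path) -> np.ndarray:
    """Load a depth vector written alongside an mtx-dir."""
    return np.loadtxt(path, dtype=np.int64, ndmin=1)


def top_expressed_genes(cm: CountMatrix, k: int) -> CountMatrix:
    """Keep the ``k`` genes with highest mean depth-normalized expression.

    Expression level of gene ``j`` is the mean over cells of ``x_ij / s_i``.
    Sequencing depths are *not* recomputed: they stay the totals of the full
    gene set, as the measurement model requires.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > cm.n_genes:
        raise ValueError(f"k={k} exceeds number of genes ({cm.n_genes})")
    mean_norm = (cm.counts / cm.depths[:, None]).mean(axis=0)
    # stable sort so that ties keep the original gene order
    order = np.argsort(-mean_norm, kind="stable")[:k]
    return cm.subset_genes(np.sort(order))
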