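"""Sparse cells-by-genes count matrix container and format plumbing.

Reads/writes the 10x Genomics sparse trio (matrix.mtx in MatrixMarket
coordinate format with 1-based indices, features.tsv, barcodes.tsv — the
matrix stored genes-by-cells as 10x does) and dense delimited text
(cells in rows, genes in columns).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = ["CountMatrix", "read_10x", "write_10x", "read_dense", "write_dense"]


@dataclass
class CountMatrix:
    """Non-negative integer counts, cells in rows and genes in columns.

    Gene symbols and cell barcodes are ordered and unique; duplicate gene
    symbols are rejected at construction.
    """

    counts: sp.csr_matrix
    gene_symbols: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_symbols = list(self.gene_symbols)
        self.barcodes = list(self.barcodes)
        n_cells, n_genes = self.counts.shape
        if n_genes != len(self.gene_symbols):
            raise ValueError(
                f"matrix has {n_genes} gene columns but "
                f"{len(self.gene_symbols)} gene symbols"
            )
        if n_cells != len(self.barcodes):
            raise ValueError(
                f"matrix has {n_cells} cell rows but "
                f"{len(self.barcodes)} barcodes"
            )
        if len(set(self.gene_symbols)) != n_genes:
            dupes = pd.Index(self.gene_symbols)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate gene symbols: {dupes}")
        if len(set(self.barcodes)) != n_cells:
            raise ValueError("duplicate cell barcodes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        self._gene_index = {g: i for i, g in enumerate(self.gene_symbols)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, symbol: str) -> int:
        return self._gene_index[symbol]

    def has_gene(self, symbol: str) -> bool:
        return symbol in self._gene_index

    def gene_counts(self, symbol: str) -> np.ndarray:
        """Dense per-cell count vector for one gene."""
        j = self._gene_index[symbol]
        return np.asarray(self.counts[:, j].todense()).ravel()

    def total_counts(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_detected(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            counts=self.counts[idx],
            gene_symbols=self.gene_symbols,
            barcodes=[self.barcodes[i] for i in idx],
        )

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (cells × genes)."""
        import anndata as ad

        return ad.AnnData(
            X=self.counts.copy(),
            obs=pd.DataFrame(index=pd.Index(self.barcodes, name="barcode")),
            var=pd.DataFrame(index=pd.Index(self.gene_symbols, name="gene")),
        )


def read_10x(directory: str | Path) -> CountMatrix:
    """Read a 10x sparse trio directory (matrix.mtx, features.tsv, barcodes.tsv).

    ``features.tsv`` may have one column (symbol) or the 10x three-column
    layout (id, symbol, feature type); ``genes.tsv`` is accepted as an alias.
    """
    directory = Path(directory)
    mtx_path = directory / "matrix.mtx"
    features_path = directory / "features.tsv"
    if not features_path.exists():
        features_path = directory / "genes.tsv"
    barcodes_path = directory / "barcodes.tsv"
    for p in (mtx_path, features_path, barcodes_path):
        if not p.exists():
            raise FileNotFoundError(f"missing 10x input file: {p}")

    mat = sp.csr_matrix(mmread(str(mtx_path)))  # genes x cells (10x layout)
    features = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
    symbols = features.iloc[:, 1 if features.shape[1] > 1 else 0].tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)
    barcodes = barcodes.iloc[:, 0].tolist()
    return CountMatrix(
        counts=mat.T.astype(np.int64), gene_symbols=symbols, barcodes=barcodes
    )


def write_10x(matrix: CountMatrix, directory: str | Path) -> None:
    """Write the 10x sparse trio (matrix stored genes × cells, 1-based mtx)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(
        str(directory / "matrix.mtx"),
        sp.coo_matrix(matrix.counts.T),
        field="integer",
    )
    with open(directory / "features.tsv", "w") as fh:
        for g in matrix.gene_symbols:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(directory / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(matrix.barcodes) + "\n")


def read_dense(path: str | Path, sep: str = ",") -> CountMatrix:
    """Read dense delimited text: cells in rows, genes in columns, both labelled."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return CountMatrix(
        counts=sp.csr_matrix(df.to_numpy(dtype=np.int64)),
        gene_symbols=[str(c) for c in df.columns],
        barcodes=[str(i) for i in df.index],
    )


def write_dense(matrix: CountMatrix, path: str | Path, sep: str = ",") -> None:
    df = pd.DataFrame(
        matrix.counts.toarray(),
        index=matrix.barcodes,
        columns=matrix.gene_symbols,
    )
    df.to_csv(path, sep=sep)


def from_dataframe(df: pd.DataFrame) -> CountMatrix:
    """Build a CountMatrix from a cells × genes DataFrame."""
    return CountMatrix(
        counts=sp.csr_matrix(df.to_numpy(dtype=np.int64)),
        gene_symbols=[str(c) for c in df.columns],
        barcodes=[str(i) for i in df.index],
    )
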