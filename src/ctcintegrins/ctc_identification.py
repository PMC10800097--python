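"""Barcode QC filtering and epithelial-marker CTC identification.

Circulating tumor cells (CTCs) in a CD45-depleted single-cell matrix are
identified transcriptionally: a cell is called a CTC when at least one
epithelial marker gene (keratins, EPCAM, MUC1, CDH1) is positively
expressed.  "Positive" defaults to a raw count of at least 1; the threshold
is configurable because no universal convention exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .matrix import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "MarkerPanel",
    "QCReport",
    "MarkerReport",
    "DEFAULT_EPITHELIAL_MARKERS",
    "qc_filter",
    "identify_ctcs",
    "write_ctc_mask",
]

#: Epithelial marker genes used for CTC calling: keratins 5/7/8/14/18,
#: EPCAM, MUC1 and E-cadherin.
DEFAULT_EPITHELIAL_MARKERS = (
    "KRT5", "KRT7", "KRT8", "KRT14", "KRT18", "EPCAM", "MUC1", "CDH1",
)


class MarkerPanelError(ValueError):
    """Raised when none of the marker-panel genes is present in the matrix."""


@dataclass(frozen=True)
class QCThresholds:
    """Barcode quality-control cutoffs.

    Defaults (min_umi=500, min_genes=200, max_mito_fraction=0.20) are
    conventional starting points for 10x data; they are deliberately
    config-exposed since appropriate values are dataset-dependent.
    """

    min_umi: int = 500
    min_genes: int = 200
    max_mito_fraction: float = 0.20
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_umi < 0 or self.min_genes < 0:
            raise ValueError("min_umi and min_genes must be >= 0")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")


@dataclass(frozen=True)
class MarkerPanel:
    """Marker genes plus the raw-count positivity threshold (>= 1)."""

    genes: tuple[str, ...] = DEFAULT_EPITHELIAL_MARKERS
    positivity_threshold: int = 1

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("marker panel must not be empty")
        if self.positivity_threshold < 1:
            raise ValueError("positivity_threshold must be >= 1")


@dataclass
class QCReport:
    n_before: int
    n_after: int
    n_removed: int
    fraction_removed: float
    thresholds: QCThresholds

    def as_dict(self) -> dict:
        return {
            "n_before": self.n_before,
            "n_after": self.n_after,
            "n_removed": self.n_removed,
            "fraction_removed": self.fraction_removed,
            "min_umi": self.thresholds.min_umi,
            "min_genes": self.thresholds.min_genes,
            "max_mito_fraction": self.thresholds.max_mito_fraction,
            "mito_prefix": self.thresholds.mito_prefix,
        }


@dataclass
class MarkerReport:
    n_cells: int
    n_ctc: int
    per_marker_positive: dict[str, int] = field(default_factory=dict)
    missing_genes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "n_ctc": self.n_ctc,
            "per_marker_positive": dict(self.per_marker_positive),
            "missing_genes": list(self.missing_genes),
        }


def qc_filter(
    matrix: CountMatrix, thresholds: QCThresholds | None = None
) -> tuple[CountMatrix, QCReport]:
    """Filter barcodes by total UMIs, detected genes and mitochondrial fraction.

    A cell is retained when total UMIs >= min_umi, detected genes >=
    min_genes and the fraction of UMIs from genes whose symbol starts with
    ``mito_prefix`` is <= max_mito_fraction.  Cells with zero counts have a
    mitochondrial fraction of 0 by convention (they fail min_umi > 0 anyway).

    Removing every cell is reported (``n_after == 0``), not raised.
    """
    if matrix.n_cells == 0:
        raise ValueError("cannot QC-filter an empty matrix")
    thresholds = thresholds or QCThresholds()

    totals = matrix.total_counts()
    n_genes = matrix.genes_detected()
    mito_cols = [
        i for i, g in enumerate(matrix.gene_symbols)
        if g.upper().startswith(thresholds.mito_prefix.upper())
    ]
    if mito_cols:
        mito_totals = np.asarray(
            matrix.counts[:, mito_cols].sum(axis=1)
        ).ravel()
    else:
        mito_totals = np.zeros(matrix.n_cells)
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_frac = np.where(totals > 0, mito_totals / np.maximum(totals, 1), 0.0)

    keep = (
        (totals >= thresholds.min_umi)
        & (n_genes >= thresholds.min_genes)
        & (mito_frac <= thresholds.max_mito_fraction)
    )
    filtered = matrix.subset_cells(keep)
    n_removed = matrix.n_cells - filtered.n_cells
    report = QCReport(
        n_before=matrix.n_cells,
        n_after=filtered.n_cells,
        n_removed=n_removed,
        fraction_removed=n_removed / matrix.n_cells,
        thresholds=thresholds,
    )
    if filtered.n_cells == 0:
        logger.warning("QC removed every barcode (%d cells)", matrix.n_cells)
    return filtered, report


def identify_ctcs(
    matrix: CountMatrix, panel: MarkerPanel | None = None
) -> tuple[np.ndarray, MarkerReport]:
    """Flag cells positive for at least one epithelial marker gene.

    Returns a boolean mask over cells (True = CTC) and a report with
    per-marker positive-cell counts.  Panel genes absent from the matrix are
    reported but not fatal; if *none* is present a
    :class:`MarkerPanelError` is raised naming the panel.
    """
    panel = panel or MarkerPanel()
    present = [g for g in panel.genes if matrix.has_gene(g)]
    missing = [g for g in panel.genes if not matrix.has_gene(g)]
    if not present:
        raise MarkerPanelError(
            f"none of the marker panel genes {list(panel.genes)} is present "
            "in the matrix"
        )
    if missing:
        logger.warning("marker genes absent from matrix: %s", missing)

    mask = np.zeros(matrix.n_cells, dtype=bool)
    per_marker: dict[str, int] = {}
    for gene in present:
        positive = matrix.gene_counts(gene) >= panel.positivity_threshold
        per_marker[gene] = int(positive.sum())
        mask |= positive
    for gene in missing:
        per_marker[gene] = 0
    report = MarkerReport(
        n_cells=matrix.n_cells,
        n_ctc=int(mask.sum()),
        per_marker_positive=per_marker,
        missing_genes=missing,
    )
    return mask, report


def write_ctc_mask(
    matrix: CountMatrix, mask: np.ndarray, path: str | Path
) -> None:
    """Write the CTC mask as two-column TSV (barcode, is_ctc)."""
    with open(path, "w") as fh:
        fh.write("barcode\tis_ctc\n")
        for barcode, flag in zip(matrix.barcodes, mask):
            fh.write(f"{barcode}\t{'true' if flag else 'false'}\n")
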