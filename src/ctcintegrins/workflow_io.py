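"""Run configuration and the end-to-end pipeline.

Stage order: barcode QC -> CTC identification -> integrin-group
classification -> panel frequency profiling -> group-vs-reference Fisher
tests -> rank-sum differential expression -> gene-set overlap enrichment.
All stage outputs are written as schema-stable TSV/JSON under the output
directory, plus a ``report.json`` capturing versions, seed, parameters and
the headline summaries, so every run is reproducible from its manifest.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .ctc_identification import (
    MarkerPanel,
    MarkerPanelError,
    QCThresholds,
    identify_ctcs,
    qc_filter,
    write_ctc_mask,
)
from .functional_profiling import (
    compare_vs_reference,
    default_panel,
    load_panel,
    overlap_enrichment,
    panel_frequencies,
    rank_de_genes,
    read_gmt,
    significant_counts,
    write_profiles,
)
from .group_classifier import classify_all, write_assignments
from .integrin_knowledge import build_pairing_table, load_pairing_table
from .matrix import read_10x, read_dense

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A hard, user-facing pipeline failure (missing input, empty CTC set...)."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML/JSON-loadable)."""

    matrix_path: str = ""
    fmt: str = "10x"  # "10x" or "csv"
    outdir: str = "ctcintegrins_out"
    csv_sep: str = ","
    # QC
    min_umi: int = 500
    min_genes: int = 200
    max_mito_fraction: float = 0.20
    mito_prefix: str = "MT-"
    skip_qc: bool = False
    # CTC identification
    marker_genes: tuple[str, ...] = ()
    positivity_threshold: int = 1
    exclude_ptprc_positive: bool = False
    # profiling
    panel_path: str | None = None
    pairing_table_path: str | None = None
    gene_sets_path: str | None = None
    reference_group: int = 9
    target_group: int = 8
    alpha: float = 0.05
    top_n: int = 50
    universe_size: int | None = None
    test_method: str = "fisher"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fmt not in ("10x", "csv"):
            raise ValueError(f"fmt must be '10x' or 'csv', got {self.fmt!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from a YAML (or JSON) mapping, with keyword overrides."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "marker_genes" in data and data["marker_genes"]:
            data["marker_genes"] = tuple(data["marker_genes"])
        return cls(**data)

    def qc_thresholds(self) -> QCThresholds:
        return QCThresholds(
            min_umi=self.min_umi,
            min_genes=self.min_genes,
            max_mito_fraction=self.max_mito_fraction,
            mito_prefix=self.mito_prefix,
        )

    def marker_panel(self) -> MarkerPanel:
        if self.marker_genes:
            return MarkerPanel(
                genes=tuple(self.marker_genes),
                positivity_threshold=self.positivity_threshold,
            )
        return MarkerPanel(positivity_threshold=self.positivity_threshold)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write all outputs under ``config.outdir``.

    Returns the run report (also written as ``report.json``).  Hard errors
    (missing inputs, no marker genes in the matrix, empty CTC set) raise
    :class:`PipelineError` with a distinct message.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    matrix_path = Path(config.matrix_path)
    if not matrix_path.exists():
        raise PipelineError(f"input matrix not found: {matrix_path}")
    try:
        if config.fmt == "10x":
            matrix = read_10x(matrix_path)
        else:
            matrix = read_dense(matrix_path, sep=config.csv_sep)
    except FileNotFoundError as exc:
        raise PipelineError(str(exc)) from exc
    except Exception as exc:  # malformed input
        raise PipelineError(
            f"failed to parse input matrix {matrix_path}: {exc}"
        ) from exc
    logger.info("loaded %d cells x %d genes", matrix.n_cells, matrix.n_genes)

    if config.skip_qc:
        filtered, qc_report = matrix, None
    else:
        filtered, qc_report = qc_filter(matrix, config.qc_thresholds())
        if filtered.n_cells == 0:
            raise PipelineError("QC removed every barcode")

    panel = config.marker_panel()
    try:
        ctc_mask, marker_report = identify_ctcs(filtered, panel)
    except MarkerPanelError as exc:
        raise PipelineError(str(exc)) from exc
    if config.exclude_ptprc_positive and filtered.has_gene("PTPRC"):
        ctc_mask &= filtered.gene_counts("PTPRC") < panel.positivity_threshold
    if ctc_mask.sum() == 0:
        raise PipelineError("no CTCs identified by the marker panel")
    write_ctc_mask(filtered, ctc_mask, outdir / "ctc_mask.tsv")

    pairing = (
        load_pairing_table(config.pairing_table_path)
        if config.pairing_table_path
        else build_pairing_table()
    )
    labels, summary = classify_all(
        filtered, ctc_mask, pairing, config.positivity_threshold
    )
    write_assignments(labels, summary, outdir)

    gene_panel = (
        load_panel(config.panel_path) if config.panel_path else default_panel()
    )
    freq = panel_frequencies(
        filtered.subset_cells(ctc_mask),
        labels,
        gene_panel,
        config.positivity_threshold,
    )
    tests = compare_vs_reference(
        freq,
        reference_group=config.reference_group,
        alpha=config.alpha,
        method=config.test_method,
    )

    group_sizes = summary.group_sizes
    de = None
    if (group_sizes.get(config.target_group, 0) > 0
            and group_sizes.get(config.reference_group, 0) > 0):
        de = rank_de_genes(
            filtered.subset_cells(ctc_mask),
            labels,
            target_group=config.target_group,
            reference_group=config.reference_group,
            top_n=config.top_n,
        )
    else:
        logger.warning(
            "target group %d or reference group %d empty; DE skipped",
            config.target_group, config.reference_group,
        )

    enrichment = None
    if config.gene_sets_path and de is not None:
        gene_sets = read_gmt(config.gene_sets_path)
        query = de.loc[de["direction"] == "up", "gene"].tolist()
        universe = config.universe_size or int(
            (filtered.counts.sum(axis=0) > 0).sum()
        )
        enrichment = overlap_enrichment(query, gene_sets, universe)

    write_profiles(freq, tests, outdir, de=de, enrichment=enrichment)

    report = {
        "package_version": __version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "qc": qc_report.as_dict() if qc_report else None,
        "markers": marker_report.as_dict(),
        "group_summary": summary.as_dict(),
        "significant_counts": {
            str(k): v for k, v in significant_counts(tests).items()
        },
        "n_top_de_genes": 0 if de is None else len(de),
        "n_enriched_sets": 0 if enrichment is None else len(enrichment),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
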