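"""Synthetic CTC cohorts for end-to-end testing without any download.

Two generators:

* :func:`build_fixture` — a deterministic 445-CTC census fixture embedded
  among marker-negative background cells.  The integrin-subunit
  combinations of the heterodimer-capable cells (groups 3-8) follow a
  published census of breast-cancer CTCs; groups 1 (non-complementary
  mixtures) and 2 (alpha-only) are drawn from validated pattern pools
  restricted to the 14 subunit genes observed in that census.  Counts for
  expressed integrin genes are 1 — the downstream analysis is set-based.
* :func:`generate_cohort` — stochastic cohorts with planted per-group
  Bernoulli positivity rates for the 36-gene tumor-progression panel and a
  set of planted differentially expressed genes, with negative-binomial
  counts for positive genes.

Every cell additionally carries a seeded Poisson "null transcriptome"
(240 synthetic ``GENEnnnn`` genes, mean 3) and three MT- genes, so that
conventional QC thresholds (total UMIs, detected genes, mitochondrial
fraction) are exercised meaningfully.  Both generators are fully
reproducible from their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .ctc_identification import DEFAULT_EPITHELIAL_MARKERS
from .functional_profiling import DEFAULT_PANEL_CATEGORIES, GenePanel, default_panel
from .integrin_knowledge import (
    ALPHA_GENES,
    BETA_GENES,
    PairingTable,
    build_pairing_table,
    infer_heterodimers,
)
from .matrix import CountMatrix, write_10x

__all__ = [
    "FixtureSpec",
    "CohortParams",
    "CENSUS_COMBINATIONS",
    "DEFAULT_GROUP_SIZES",
    "OBSERVED_SUBUNITS",
    "build_fixture",
    "generate_cohort",
    "write_cohort",
]

#: The 14 integrin subunit genes observed in the emulated CTC census
#: (9 alpha + 5 beta).
OBSERVED_SUBUNITS = (
    "ITGA2", "ITGA2B", "ITGA4", "ITGA5", "ITGA6",
    "ITGAE", "ITGAL", "ITGAM", "ITGAV",
    "ITGB1", "ITGB2", "ITGB3", "ITGB4", "ITGB5",
)

#: Per-combination census of the heterodimer-capable groups (3-8):
#: (group, expressed subunit genes, number of cells).  One combination is a
#: documented correction: the group-5 row printed with ITGA2 alongside a
#: called alpha2b-beta3 dimer is emitted with ITGA2B (alpha2 cannot
#: partner beta3).
CENSUS_COMBINATIONS: tuple[tuple[int, tuple[str, ...], int], ...] = (
    (3, ("ITGB1", "ITGA2"), 1),
    (3, ("ITGB1", "ITGA4", "ITGAE"), 2),
    (3, ("ITGB1", "ITGA6"), 4),
    (3, ("ITGB1", "ITGAV"), 1),
    (4, ("ITGB2", "ITGAM"), 1),
    (4, ("ITGB2", "ITGAM", "ITGAL"), 1),
    (5, ("ITGB3", "ITGA2B"), 9),
    (5, ("ITGB3", "ITGA2B", "ITGA5"), 1),
    (5, ("ITGB3", "ITGA2B", "ITGAE"), 1),  # corrected: ITGA2B, not ITGA2
    (6, ("ITGB1", "ITGB2", "ITGAE", "ITGA2B", "ITGA4"), 1),
    (6, ("ITGB1", "ITGB2", "ITGAE", "ITGAL"), 1),
    (6, ("ITGB1", "ITGB2", "ITGB3", "ITGAE", "ITGAL"), 1),
    (6, ("ITGB1", "ITGB3", "ITGB5", "ITGA2B"), 9),
    (6, ("ITGB1", "ITGB3", "ITGB5", "ITGA2B", "ITGA6"), 1),
    (6, ("ITGB1", "ITGB3", "ITGB5", "ITGA2B", "ITGA2"), 2),
    (6, ("ITGB1", "ITGB3", "ITGB5", "ITGA2B", "ITGAE"), 1),
    (6, ("ITGB1", "ITGB3", "ITGB5", "ITGA2B", "ITGAM"), 1),
    (6, ("ITGB1", "ITGB3", "ITGB5", "ITGA2B", "ITGA2", "ITGA6",
         "ITGAE", "ITGAM"), 1),
    (6, ("ITGB1", "ITGB3", "ITGB5", "ITGA2", "ITGA5"), 1),
    (6, ("ITGB1", "ITGB3", "ITGA2B"), 13),
    (6, ("ITGB1", "ITGB3", "ITGA2B", "ITGA6"), 2),
    (6, ("ITGB1", "ITGB3", "ITGA2B", "ITGAV", "ITGAM"), 1),
    (6, ("ITGB1", "ITGB3", "ITGA6"), 1),
    (6, ("ITGB3", "ITGB5", "ITGA2B"), 2),
    (7, ("ITGB4",), 1),
    (7, ("ITGB4", "ITGB2"), 1),
    (7, ("ITGB4", "ITGB1", "ITGA4", "ITGAE"), 1),
    (8, ("ITGB4", "ITGB1", "ITGA6", "ITGAE", "ITGAV"), 1),
    (8, ("ITGB4", "ITGB1", "ITGB3", "ITGB5", "ITGA2", "ITGA5",
         "ITGA6", "ITGAV"), 1),
    (8, ("ITGB4", "ITGB1", "ITGA2", "ITGA5", "ITGA6", "ITGAV"), 1),
    (8, ("ITGB4", "ITGB1", "ITGA2", "ITGA5", "ITGA6", "ITGAE", "ITGAV"), 2),
)

#: Default per-group CTC counts (groups 1-9, summing to 445).
DEFAULT_GROUP_SIZES = (143, 81, 8, 2, 11, 38, 3, 5, 154)

#: Non-complementary alpha+beta pattern pool for group 1 (validated: every
#: pattern contains both chains, no ITGB4 and yields zero dimers).
DEFAULT_GROUP1_POOL: tuple[tuple[str, ...], ...] = (
    ("ITGA5", "ITGB2"),
    ("ITGA6", "ITGB3"),
    ("ITGAE", "ITGB1"),
    ("ITGA2", "ITGB2"),
    ("ITGAL", "ITGB1"),
    ("ITGAM", "ITGB1"),
    ("ITGAM", "ITGB3"),
    ("ITGA4", "ITGB2"),
    ("ITGA2", "ITGB5"),
    ("ITGAE", "ITGB3", "ITGA4"),
    ("ITGAL", "ITGB5"),
    ("ITGA5", "ITGB2", "ITGAE"),
)

#: Alpha-only pattern pool for group 2.
DEFAULT_GROUP2_POOL: tuple[tuple[str, ...], ...] = (
    ("ITGA5",),
    ("ITGA2",),
    ("ITGA6",),
    ("ITGA4",),
    ("ITGAE",),
    ("ITGAL",),
    ("ITGAM",),
    ("ITGAV",),
    ("ITGA2B",),
    ("ITGAM", "ITGAL"),
    ("ITGA4", "ITGAE"),
    ("ITGA5", "ITGA6"),
)

#: Planted upregulated genes outside the panel (plus VIM, which sits in the
#: panel's EMT category) used for the differential-expression route.
DEFAULT_DE_GENES = (
    "WWTR1", "CAV1", "VWF", "IGFBP7", "POSTN", "FN1", "COL3A1",
    "ANXA2", "MMRN1", "MGP", "TIMP1", "LMNA", "VIM", "KLF6",
)

_MITO_GENES = ("MT-CO1", "MT-ND1", "MT-CYB")
_N_FILLER = 240
_FILLER_GENES = tuple(f"GENE{i:04d}" for i in range(1, _N_FILLER + 1))
#: Non-EPCAM markers cycled over fixture CTCs.
_FIXTURE_MARKER_CYCLE = ("KRT18", "KRT8", "KRT7", "KRT5", "KRT14",
                         "MUC1", "CDH1")
#: Markers cycled in stochastic cohorts: only markers outside the 36-gene
#: panel, so planted panel rates are not perturbed.
_COHORT_MARKER_CYCLE = ("KRT5", "KRT7", "KRT14")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the deterministic census fixture.

    Defaults encode the emulated census: 445 CTCs split 143/81/8/2/11/38/
    3/5/154 over groups 1-9, 1,000 marker-negative background cells, an
    EPCAM-positive CTC fraction of 0.026 and an MKI67-positive fraction of
    0.0088 (both rounded to whole cells).
    """

    group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES
    combinations: tuple[tuple[int, tuple[str, ...], int], ...] = (
        CENSUS_COMBINATIONS
    )
    group1_pool: tuple[tuple[str, ...], ...] = DEFAULT_GROUP1_POOL
    group2_pool: tuple[tuple[str, ...], ...] = DEFAULT_GROUP2_POOL
    n_background: int = 1000
    epcam_fraction: float = 0.026
    mki67_fraction: float = 0.0088

    def __post_init__(self) -> None:
        if len(self.group_sizes) != 9:
            raise ValueError("group_sizes must have 9 entries")
        if any(n < 0 for n in self.group_sizes) or self.n_background < 0:
            raise ValueError("cell counts must be >= 0")
        for frac, name in ((self.epcam_fraction, "epcam_fraction"),
                           (self.mki67_fraction, "mki67_fraction")):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        table = build_pairing_table()
        for pattern in self.group1_pool:
            genes = set(pattern)
            if infer_heterodimers(genes, table).dimers:
                raise ValueError(
                    f"group-1 pattern {pattern} contains a complementary pair"
                )
            if "ITGB4" in genes:
                raise ValueError(f"group-1 pattern {pattern} contains ITGB4")
            if not (genes & ALPHA_GENES and genes & BETA_GENES):
                raise ValueError(
                    f"group-1 pattern {pattern} must mix alpha and beta genes"
                )
        for pattern in self.group2_pool:
            if set(pattern) & BETA_GENES:
                raise ValueError(
                    f"group-2 pattern {pattern} contains a beta gene"
                )
        for g in (3, 4, 5, 6, 7, 8):
            expected = self.group_sizes[g - 1]
            actual = sum(n for grp, _, n in self.combinations if grp == g)
            # a zero group size drops that group's combination rows entirely
            if expected not in (0, actual):
                raise ValueError(
                    f"group {g}: combination rows sum to {actual} cells but "
                    f"group_sizes expects {expected}"
                )

    @property
    def n_ctc(self) -> int:
        return sum(self.group_sizes)


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the stochastic cohort generator.

    ``base_rate`` is the Bernoulli positivity rate of every panel gene in
    every group; ``effect_genes`` (26 of the 36 panel genes by default:
    the stemness, EMT, laminin and invasion categories) are elevated to
    ``effect_rate`` in the alpha6-beta4 co-expression group (8).
    ``de_genes`` outside the panel are planted at ``de_positivity`` with a
    higher negative-binomial mean in group 8 and at ``de_base_positivity``
    elsewhere.  Positive genes draw NB(mean, dispersion) counts floored at
    1 (variance = mean + dispersion * mean^2); negative genes are 0.
    """

    group_sizes: tuple[int, ...] = (500,) * 9
    base_rate: float = 0.02
    effect_rate: float = 0.4
    effect_genes: tuple[str, ...] | None = None
    de_genes: tuple[str, ...] = DEFAULT_DE_GENES
    de_positivity: float = 0.6
    de_base_positivity: float = 0.05
    nb_mean: float = 3.0
    nb_dispersion: float = 0.5
    de_nb_mean: float = 8.0
    n_background: int = 0

    def __post_init__(self) -> None:
        if len(self.group_sizes) != 9:
            raise ValueError("group_sizes must have 9 entries")
        if any(n < 0 for n in self.group_sizes) or self.n_background < 0:
            raise ValueError("group_sizes and n_background must be >= 0")
        for name in ("base_rate", "effect_rate", "de_positivity",
                     "de_base_positivity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("nb_mean", "de_nb_mean", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        panel_genes = set(default_panel().genes)
        if self.effect_genes is not None:
            unknown = set(self.effect_genes) - panel_genes
            if unknown:
                raise ValueError(
                    f"effect_genes not in the panel: {sorted(unknown)}"
                )

    def resolved_effect_genes(self) -> tuple[str, ...]:
        if self.effect_genes is not None:
            return self.effect_genes
        cats = DEFAULT_PANEL_CATEGORIES
        return (cats["stemness"] + cats["emt"] + cats["laminins"]
                + cats["invasion"])


def _gene_universe() -> list[str]:
    ordered = (
        list(OBSERVED_SUBUNITS)
        + list(DEFAULT_EPITHELIAL_MARKERS)
        + [g for genes in DEFAULT_PANEL_CATEGORIES.values() for g in genes]
        + list(DEFAULT_DE_GENES)
        + ["PTPRC"]
        + list(_MITO_GENES)
        + list(_FILLER_GENES)
    )
    return list(dict.fromkeys(ordered))


def _base_layers(
    n_cells: int, genes: list[str], rng: np.random.Generator
) -> np.ndarray:
    """Poisson null transcriptome plus mitochondrial counts for all cells."""
    X = np.zeros((n_cells, len(genes)), dtype=np.int64)
    gene_idx = {g: j for j, g in enumerate(genes)}
    filler_cols = [gene_idx[g] for g in _FILLER_GENES]
    X[:, filler_cols] = rng.poisson(3.0, size=(n_cells, len(filler_cols)))
    mito_cols = [gene_idx[g] for g in _MITO_GENES]
    X[:, mito_cols] = rng.poisson(25.0, size=(n_cells, len(mito_cols)))
    return X


def build_fixture(
    spec: FixtureSpec | None = None, seed: int = 0
) -> tuple[CountMatrix, pd.DataFrame]:
    """Build the deterministic census fixture.

    Returns the count matrix (CTCs first, then background cells) and a
    truth table with one row per cell: barcode, is_ctc, true_group
    (0 for background), expressed integrin genes, EPCAM/MKI67 positivity.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(seed)
    genes = _gene_universe()
    gene_idx = {g: j for j, g in enumerate(genes)}
    n_ctc = spec.n_ctc
    n_cells = n_ctc + spec.n_background

    # per-CTC integrin gene sets, in group order 1..9
    patterns: list[tuple[int, tuple[str, ...]]] = []
    for g in range(1, 10):
        size = spec.group_sizes[g - 1]
        if g in (1, 2):
            pool = spec.group1_pool if g == 1 else spec.group2_pool
            idx = rng.integers(0, len(pool), size=size)
            patterns += [(g, pool[i]) for i in idx]
        elif g == 9:
            patterns += [(g, ())] * size
        elif size > 0:
            for grp, combo, n in spec.combinations:
                if grp == g:
                    patterns += [(g, combo)] * n

    X = _base_layers(n_cells, genes, rng)
    for i, (_, combo) in enumerate(patterns):
        for gene in combo:
            X[i, gene_idx[gene]] = 1

    # epithelial markers: every CTC gets one cycling non-EPCAM marker; a
    # rounded fraction additionally gets EPCAM; background cells get none.
    for i in range(n_ctc):
        marker = _FIXTURE_MARKER_CYCLE[i % len(_FIXTURE_MARKER_CYCLE)]
        X[i, gene_idx[marker]] = max(X[i, gene_idx[marker]], 1)
    n_epcam = round(spec.epcam_fraction * n_ctc)
    epcam_cells = rng.choice(n_ctc, size=n_epcam, replace=False)
    X[epcam_cells, gene_idx["EPCAM"]] = 1
    n_mki67 = round(spec.mki67_fraction * n_ctc)
    mki67_cells = rng.choice(n_ctc, size=n_mki67, replace=False)
    X[mki67_cells, gene_idx["MKI67"]] = 1

    # background: CD45-depletion residue; PTPRC-positive, marker-negative
    X[n_ctc:, gene_idx["PTPRC"]] = 2

    barcodes = [f"CTC{i + 1:04d}" for i in range(n_ctc)]
    barcodes += [f"BG{i + 1:04d}" for i in range(spec.n_background)]
    matrix = CountMatrix(
        counts=sp.csr_matrix(X), gene_symbols=genes, barcodes=barcodes
    )
    epcam_set = set(epcam_cells.tolist())
    mki67_set = set(mki67_cells.tolist())
    truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "is_ctc": [i < n_ctc for i in range(n_cells)],
            "true_group": [g for g, _ in patterns] + [0] * spec.n_background,
            "integrin_genes": [
                ";".join(sorted(c)) for _, c in patterns
            ] + [""] * spec.n_background,
            "epcam_positive": [
                i in epcam_set for i in range(n_ctc)
            ] + [False] * spec.n_background,
            "mki67_positive": [
                i in mki67_set for i in range(n_ctc)
            ] + [False] * spec.n_background,
        }
    ).set_index("barcode")
    return matrix, truth


def _nb_counts(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    """Negative-binomial counts floored at 1 (variance = mean + disp*mean^2)."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p, size=size)
    return np.maximum(counts, 1)


def generate_cohort(
    params: CohortParams | None = None, seed: int = 0
) -> tuple[CountMatrix, pd.DataFrame]:
    """Generate a stochastic cohort with planted group effects.

    Integrin patterns are sampled per group from the census combination
    rows (weighted by their census cell counts) and from the group-1/2
    pattern pools; panel and DE genes follow the per-group rates in
    ``params``.  Fully reproducible from ``seed``.
    """
    params = params or CohortParams()
    rng = np.random.default_rng(seed)
    genes = _gene_universe()
    gene_idx = {g: j for j, g in enumerate(genes)}
    panel = default_panel()
    effect_genes = set(params.resolved_effect_genes())
    panel_genes = set(panel.genes)
    de_extra = [g for g in params.de_genes if g not in panel_genes]

    spec = FixtureSpec()  # pattern pools + census combination weights
    group_rows = {
        g: [(combo, n) for grp, combo, n in spec.combinations if grp == g]
        for g in (3, 4, 5, 6, 7, 8)
    }

    n_ctc = sum(params.group_sizes)
    n_cells = n_ctc + params.n_background
    X = _base_layers(n_cells, genes, rng)
    labels: list[int] = []
    pattern_strs: list[str] = []

    i = 0
    for g in range(1, 10):
        size = params.group_sizes[g - 1]
        # integrin patterns
        if g in (1, 2):
            pool = spec.group1_pool if g == 1 else spec.group2_pool
            choice = rng.integers(0, len(pool), size=size)
            cell_patterns = [pool[c] for c in choice]
        elif g == 9:
            cell_patterns = [()] * size
        else:
            combos, weights = zip(*group_rows[g])
            w = np.asarray(weights, dtype=float)
            choice = rng.choice(len(combos), size=size, p=w / w.sum())
            cell_patterns = [combos[c] for c in choice]

        rows = np.arange(i, i + size)
        for row, combo in zip(rows, cell_patterns):
            for gene in combo:
                X[row, gene_idx[gene]] = 1
        # epithelial markers (non-panel markers only)
        for row in rows:
            marker = _COHORT_MARKER_CYCLE[row % len(_COHORT_MARKER_CYCLE)]
            X[row, gene_idx[marker]] = max(X[row, gene_idx[marker]], 1)
        # panel genes: Bernoulli positivity, NB counts for positives
        for gene in panel.genes:
            rate = (
                params.effect_rate
                if g == 8 and gene in effect_genes
                else params.base_rate
            )
            positive = rng.random(size) < rate
            n_pos = int(positive.sum())
            if n_pos:
                X[rows[positive], gene_idx[gene]] = _nb_counts(
                    rng, params.nb_mean, params.nb_dispersion, n_pos
                )
        # planted DE genes outside the panel
        for gene in de_extra:
            if g == 8:
                rate, mean = params.de_positivity, params.de_nb_mean
            else:
                rate, mean = params.de_base_positivity, params.nb_mean
            positive = rng.random(size) < rate
            n_pos = int(positive.sum())
            if n_pos:
                X[rows[positive], gene_idx[gene]] = _nb_counts(
                    rng, mean, params.nb_dispersion, n_pos
                )
        labels += [g] * size
        pattern_strs += [";".join(sorted(c)) for c in cell_patterns]
        i += size

    X[n_ctc:, gene_idx["PTPRC"]] = 2
    barcodes = [f"SIM{i + 1:05d}" for i in range(n_ctc)]
    barcodes += [f"BG{i + 1:05d}" for i in range(params.n_background)]
    matrix = CountMatrix(
        counts=sp.csr_matrix(X), gene_symbols=genes, barcodes=barcodes
    )
    truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "is_ctc": [i < n_ctc for i in range(n_cells)],
            "true_group": labels + [0] * params.n_background,
            "integrin_genes": pattern_strs + [""] * params.n_background,
        }
    ).set_index("barcode")
    return matrix, truth


def write_cohort(
    matrix: CountMatrix,
    truth: pd.DataFrame,
    outdir: str | Path,
    params: FixtureSpec | CohortParams | None = None,
    seed: int | None = None,
) -> None:
    """Write the 10x trio, the truth TSV and a JSON parameter manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_10x(matrix, outdir)
    truth.to_csv(outdir / "truth.tsv", sep="\t")
    manifest: dict = {"seed": seed, "n_cells": matrix.n_cells,
                      "n_genes": matrix.n_genes}
    if params is not None:
        manifest["params_class"] = type(params).__name__
        manifest["params"] = json.loads(json.dumps(asdict(params), default=list))
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
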