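"""Functional profiling of CTC groups.

Four analyses over the grouped CTCs:

* per-group expressing-cell fractions for a tumor-progression gene panel
  (positivity = raw count above a threshold, each group taken as 100 %);
* per-gene two-sided Fisher exact comparison of each group against the
  no-integrin reference group, with Benjamini-Hochberg correction within
  each group across the panel;
* rank-sum (Wilcoxon/Mann-Whitney) differential expression on
  log-normalised counts between a target and a reference group;
* upper-tail hypergeometric gene-set overlap against GMT gene sets.

Fisher + BH is used for the binary frequency comparisons because group
sizes are small and the data are presence/absence; a chi-square variant is
offered as an option.  The frequency unit is the fraction of cells in a
group with a positive count, not mean expression — for rare transcripts in
shallow scRNA-seq the presence call is the robust signal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GenePanel",
    "default_panel",
    "load_panel",
    "panel_frequencies",
    "compare_vs_reference",
    "significant_counts",
    "bh_adjust",
    "rank_de_genes",
    "overlap_enrichment",
    "read_gmt",
]

#: Default 36-gene tumor-progression panel, by functional category.
#: Stemness, EMT, laminins (alpha6-beta4 ligands), invasion, chemokines /
#: proinflammatory cytokines, epithelial identity and proliferation.
DEFAULT_PANEL_CATEGORIES: dict[str, tuple[str, ...]] = {
    "stemness": ("CD44", "CD24", "PROM1", "ALDH1A1", "KLF4", "MYC"),
    "emt": ("SNAI1", "SNAI2", "ZEB1", "ZEB2", "CDH1", "CDH2", "VIM",
            "TGFB1", "EPCAM"),
    "laminins": ("LAMA4", "LAMA5", "LAMB1", "LAMB2", "LAMC1"),
    "invasion": ("RAC1", "RHOC", "ROCK1", "MMP1", "MMP2", "MMP9"),
    "chemokine_cytokine": ("IL6", "CCL2", "ACKR3", "VEGFA"),
    "epithelial": ("KRT8", "KRT10", "KRT18", "KRT19", "MUC1"),
    "proliferation": ("MKI67",),
}


@dataclass(frozen=True)
class GenePanel:
    """Named gene categories; genes must be unique across categories."""

    categories: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        all_genes = [g for genes in self.categories.values() for g in genes]
        if len(all_genes) != len(set(all_genes)):
            seen, dupes = set(), set()
            for g in all_genes:
                (dupes if g in seen else seen).add(g)
            raise ValueError(f"duplicate panel genes: {sorted(dupes)}")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for genes in self.categories.values() for g in genes)

    def category_of(self, gene: str) -> str:
        for cat, genes in self.categories.items():
            if gene in genes:
                return cat
        raise KeyError(gene)

    def __len__(self) -> int:
        return len(self.genes)


def default_panel() -> GenePanel:
    """The bundled 36-gene tumor-progression panel."""
    return GenePanel(categories=dict(DEFAULT_PANEL_CATEGORIES))


def load_panel(path: str | Path) -> GenePanel:
    """Load a panel from two-column TSV (category, gene); header optional."""
    categories: dict[str, list[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        cat, gene = line.split("\t")
        if i == 0 and cat.lower() == "category":
            continue
        categories.setdefault(cat, []).append(gene)
    return GenePanel(
        categories={k: tuple(v) for k, v in categories.items()}
    )


def save_panel(panel: GenePanel, path: str | Path) -> None:
    lines = ["category\tgene"]
    for cat, genes in panel.categories.items():
        lines += [f"{cat}\t{g}" for g in genes]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# expression frequencies and group-vs-reference tests
# ---------------------------------------------------------------------------

def panel_frequencies(
    matrix: CountMatrix,
    labels: pd.DataFrame | pd.Series,
    panel: GenePanel | None = None,
    positivity_threshold: int = 1,
) -> pd.DataFrame:
    """Per-group expressing-cell fractions for every panel gene.

    Parameters
    ----------
    labels : group labels indexed by barcode (a ``group_id`` column is used
        if a DataFrame is passed); every labelled barcode must be in the
        matrix.

    Returns a tidy DataFrame with columns group, gene, category,
    n_expressing, n_total, fraction.  Panel genes absent from the matrix
    get fraction 0 with a logged warning.
    """
    panel = panel or default_panel()
    groups = _group_series(labels)
    barcode_rows = {b: i for i, b in enumerate(matrix.barcodes)}
    missing_cells = [b for b in groups.index if b not in barcode_rows]
    if missing_cells:
        raise KeyError(
            f"{len(missing_cells)} labelled barcodes absent from the matrix "
            f"(first: {missing_cells[0]!r})"
        )

    records = []
    group_ids = sorted(groups.unique())
    group_rows = {
        g: np.array([barcode_rows[b] for b in groups.index[groups == g]])
        for g in group_ids
    }
    for gene in panel.genes:
        if matrix.has_gene(gene):
            vec = matrix.gene_counts(gene) >= positivity_threshold
        else:
            logger.warning("panel gene %s absent from matrix; fraction=0", gene)
            vec = np.zeros(matrix.n_cells, dtype=bool)
        for g in group_ids:
            rows = group_rows[g]
            n_expr = int(vec[rows].sum())
            records.append(
                {
                    "group": g,
                    "gene": gene,
                    "category": panel.category_of(gene),
                    "n_expressing": n_expr,
                    "n_total": len(rows),
                    "fraction": n_expr / len(rows) if len(rows) else np.nan,
                }
            )
    return pd.DataFrame.from_records(records)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvalues, method="fdr_bh")[1]


def compare_vs_reference(
    freq: pd.DataFrame,
    reference_group: int = 9,
    alpha: float = 0.05,
    method: str = "fisher",
) -> pd.DataFrame:
    """Test each group's per-gene expressing fraction against a reference group.

    For every (group, gene) with group != reference, a two-sided test on the
    2x2 table [[expr_g, nonexpr_g], [expr_ref, nonexpr_ref]]; BH correction
    is applied within each group across its panel genes.  ``method`` is
    ``"fisher"`` (exact, default) or ``"chi2"``.

    Empty groups are flagged ``testable=False`` with NaN statistics rather
    than fabricated values.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if method not in ("fisher", "chi2"):
        raise ValueError(f"unknown method {method!r}")
    ref = freq[freq["group"] == reference_group].set_index("gene")
    if ref.empty or int(ref["n_total"].iloc[0]) < 1:
        raise ValueError(
            f"reference group {reference_group} is absent or empty"
        )

    frames = []
    for group, sub in freq[freq["group"] != reference_group].groupby("group"):
        sub = sub.set_index("gene")
        testable = int(sub["n_total"].iloc[0]) >= 1
        rows = []
        for gene, r in sub.iterrows():
            a, b = int(r["n_expressing"]), int(r["n_total"] - r["n_expressing"])
            c = int(ref.loc[gene, "n_expressing"])
            d = int(ref.loc[gene, "n_total"] - c)
            if not testable:
                odds, p = np.nan, np.nan
            elif method == "fisher":
                odds, p = stats.fisher_exact([[a, b], [c, d]],
                                             alternative="two-sided")
            else:
                table = np.array([[a, b], [c, d]])
                if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                    odds, p = np.nan, 1.0
                else:
                    p = stats.chi2_contingency(table, correction=True)[1]
                    odds = (a * d) / (b * c) if b * c else np.inf
            rows.append(
                {
                    "group": group, "gene": gene,
                    "category": r["category"],
                    "n_expressing": a, "n_nonexpressing": b,
                    "ref_expressing": c, "ref_nonexpressing": d,
                    "fraction": r["fraction"],
                    "ref_fraction": c / (c + d) if c + d else np.nan,
                    "odds_ratio": odds, "pvalue": p,
                    "testable": testable,
                }
            )
        df = pd.DataFrame(rows)
        if testable:
            df["qvalue"] = bh_adjust(df["pvalue"].to_numpy())
            df["significant"] = df["qvalue"] < alpha
        else:
            df["qvalue"] = np.nan
            df["significant"] = False
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def significant_counts(results: pd.DataFrame) -> dict[int, str]:
    """Per-group significant-gene counts formatted ``"k/36"``."""
    out = {}
    for group, sub in results.groupby("group"):
        out[int(group)] = f"{int(sub['significant'].sum())}/{len(sub)}"
    return out


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def _log_normalize(counts: sp.spmatrix, target_sum: float = 1e4) -> np.ndarray:
    """Per-cell scaling to ``target_sum`` total counts, then log1p (dense)."""
    dense = np.asarray(counts.todense(), dtype=float)
    totals = dense.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(dense / totals * target_sum)


def rank_de_genes(
    matrix: CountMatrix,
    labels: pd.DataFrame | pd.Series,
    target_group: int = 8,
    reference_group: int = 9,
    top_n: int = 50,
) -> pd.DataFrame:
    """Rank differentially expressed genes between two groups.

    Counts are normalised per cell to a fixed total (1e4) and log1p
    transformed; each gene is tested with a two-sided Mann-Whitney rank-sum
    test, BH-corrected across the whole tested gene universe, and the top
    ``top_n`` genes by adjusted p (ties broken by raw p, then absolute mean
    difference) are returned with an up/down direction from the mean
    difference (target minus reference).
    """
    groups = _group_series(labels)
    barcode_rows = {b: i for i, b in enumerate(matrix.barcodes)}
    t_rows = [barcode_rows[b] for b in groups.index[groups == target_group]]
    r_rows = [barcode_rows[b] for b in groups.index[groups == reference_group]]
    if not t_rows or not r_rows:
        raise ValueError(
            f"both groups must be nonempty (target n={len(t_rows)}, "
            f"reference n={len(r_rows)})"
        )
    if min(len(t_rows), len(r_rows)) == 1:
        logger.warning("a compared group has a single cell; rank-sum test "
                       "degenerates")

    X = _log_normalize(matrix.counts[t_rows + r_rows, :])
    nt = len(t_rows)
    pvals = np.ones(matrix.n_genes)
    mean_diff = np.zeros(matrix.n_genes)
    for j in range(matrix.n_genes):
        x, y = X[:nt, j], X[nt:, j]
        mean_diff[j] = x.mean() - y.mean()
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            pvals[j] = 1.0  # constant gene: no information
            continue
        pvals[j] = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
    qvals = bh_adjust(pvals)
    df = pd.DataFrame(
        {
            "gene": matrix.gene_symbols,
            "pvalue": pvals,
            "qvalue": qvals,
            "mean_diff": mean_diff,
            "direction": np.where(mean_diff > 0, "up", "down"),
        }
    )
    df = df.sort_values(
        by=["qvalue", "pvalue", "mean_diff"],
        key=lambda s: -s.abs() if s.name == "mean_diff" else s,
        kind="mergesort",
    ).head(top_n)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene-set overlap enrichment
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT gene sets (tab-separated: name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def overlap_enrichment(
    query_genes: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe_size: int,
) -> pd.DataFrame:
    """Upper-tail hypergeometric overlap of a query list with gene sets.

    For each set, with N = ``universe_size``, K = set size, n = query size
    and k = overlap, p = P(X >= k) for X ~ Hypergeometric(N, K, n).  Sets
    with no gene in the query universe context are still tested; results
    are sorted by p ascending.
    """
    query = list(dict.fromkeys(query_genes))
    if not query:
        raise ValueError("query gene list is empty")
    n = len(query)
    if universe_size < n:
        raise ValueError("universe_size smaller than the query list")
    rows = []
    for name, members in gene_sets.items():
        members = set(members)
        K = len(members)
        if K == 0:
            logger.warning("gene set %s is empty; skipped", name)
            continue
        if universe_size < K:
            raise ValueError(
                f"universe_size {universe_size} smaller than set {name!r} "
                f"({K} genes)"
            )
        k = len(members.intersection(query))
        p = float(stats.hypergeom.sf(k - 1, universe_size, K, n))
        rows.append(
            {
                "set": name, "overlap": k, "query_size": n,
                "set_size": K, "universe_size": universe_size, "pvalue": p,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["pvalue", "set"], kind="mergesort")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------

def _group_series(labels: pd.DataFrame | pd.Series) -> pd.Series:
    if isinstance(labels, pd.DataFrame):
        return labels["group_id"]
    return labels


def write_profiles(
    freq: pd.DataFrame,
    tests: pd.DataFrame,
    outdir: str | Path,
    de: pd.DataFrame | None = None,
    enrichment: pd.DataFrame | None = None,
) -> None:
    """Write frequency, test, DE and enrichment tables plus the k/N summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    freq.to_csv(outdir / "panel_frequencies.tsv", sep="\t", index=False)
    tests.to_csv(outdir / "panel_tests.tsv", sep="\t", index=False)
    with open(outdir / "significant_counts.json", "w") as fh:
        json.dump(
            {str(k): v for k, v in significant_counts(tests).items()},
            fh, indent=2, sort_keys=True,
        )
    if de is not None:
        de.to_csv(outdir / "top_de_genes.tsv", sep="\t", index=False)
    if enrichment is not None:
        enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)


def frequency_heatmap(freq: pd.DataFrame, path: str | Path) -> None:
    """Optional per-group x gene expressing-fraction heat map (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = freq.pivot(index="gene", columns="group", values="fraction")
    fig, ax = plt.subplots(
        figsize=(1 + 0.6 * pivot.shape[1], 1 + 0.25 * pivot.shape[0])
    )
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="viridis",
                   vmin=0, vmax=1)
    ax.set_xticks(range(pivot.shape[1]), pivot.columns)
    ax.set_yticks(range(pivot.shape[0]), pivot.index, fontsize=6)
    ax.set_xlabel("group")
    fig.colorbar(im, ax=ax, label="fraction expressing")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
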