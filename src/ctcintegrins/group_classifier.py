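"""Rule-based assignment of CTCs to nine integrin-profile groups.

The nine groups partition CTCs by which integrin subunit genes they
express and which heterodimers those genes can form:

1. non-complementary subunit combinations (no permitted pair, mixed chains)
2. alpha subunits only
3. heterodimer(s) on beta1 with no other beta subunit
4. heterodimer(s) on beta2 with no other beta subunit
5. heterodimer(s) on beta3 with no other beta subunit
6. several beta subunits with at least one heterodimer
7. ITGB4 expressed without complementary ITGA6
8. ITGA6 and ITGB4 co-expressed (the laminin receptor alpha6-beta4)
9. no integrin subunit gene expressed

beta4 status takes precedence over the dimer logic: a cell carrying ITGB4
plus, say, an alpha4-beta1 pair is still group 7 — the classification
tracks the biologically focal alpha6-beta4 axis first.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .integrin_knowledge import (
    ALPHA_GENES,
    BETA_GENES,
    SUBUNIT_SHORT_NAMES,
    HeterodimerCall,
    PairingTable,
    build_pairing_table,
    infer_heterodimers,
    normalize_symbol,
)
from .matrix import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GroupAssignment",
    "GroupSummary",
    "assign_group",
    "classify_all",
    "summarize_heterodimer_counts",
    "write_assignments",
]

GROUP_IDS = tuple(range(1, 10))


@dataclass(frozen=True)
class GroupAssignment:
    """One cell's group label with the rule that produced it."""

    group_id: int
    rule_fired: str
    heterodimer_call: HeterodimerCall


@dataclass
class GroupSummary:
    """Cohort-level classification summary."""

    group_sizes: dict[int, int]
    dimer_counts: list[int]
    per_group_max_dimers: dict[int, int]
    per_group_min_dimers: dict[int, int]
    n_multi_dimer_outside_b4_group: int  # cells outside group 8 with >= 3 dimers
    n_cells: int
    heterodimer_capable_fraction: float  # fraction in groups 3-8
    flagged_rules: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "group_sizes": {str(k): v for k, v in self.group_sizes.items()},
            "per_group_max_dimers": {
                str(k): v for k, v in self.per_group_max_dimers.items()
            },
            "per_group_min_dimers": {
                str(k): v for k, v in self.per_group_min_dimers.items()
            },
            "n_multi_dimer_outside_b4_group":
                self.n_multi_dimer_outside_b4_group,
            "heterodimer_capable_fraction": self.heterodimer_capable_fraction,
            "flagged_rules": dict(self.flagged_rules),
        }


def assign_group(
    expressed: Iterable[str], table: PairingTable | None = None
) -> GroupAssignment:
    """Assign one cell's expressed integrin gene set to a group (1-9).

    Decision order: no genes -> 9; ITGA6+ITGB4 -> 8; ITGB4 -> 7; else infer
    dimers; with >= 1 dimer, a single beta gene maps ITGB1/ITGB2/ITGB3 to
    groups 3/4/5 (any other single beta -> 6, flagged) and multiple beta
    genes -> 6; with no dimer, alpha-only -> 2, otherwise -> 1 (beta-only
    cells land here, flagged, since no group wording covers them).
    """
    if table is None:
        table = build_pairing_table()
    genes = {normalize_symbol(s) for s in expressed}
    call = infer_heterodimers(genes, table)

    if not genes:
        return GroupAssignment(9, "no_integrins", call)
    if "ITGB4" in genes and "ITGA6" in genes:
        return GroupAssignment(8, "a6_b4_coexpressed", call)
    if "ITGB4" in genes:
        return GroupAssignment(7, "b4_without_a6", call)

    betas = genes & BETA_GENES
    if call.dimers:
        if len(betas) == 1:
            beta = next(iter(betas))
            single_beta_group = {"ITGB1": 3, "ITGB2": 4, "ITGB3": 5}
            if beta in single_beta_group:
                return GroupAssignment(
                    single_beta_group[beta],
                    f"single_beta_{SUBUNIT_SHORT_NAMES[beta]}_dimer",
                    call,
                )
            # dimer on b5/b6/b7/b8 as the only beta: closest wording is the
            # multi-beta "at least one heterodimer" group; flagged.
            return GroupAssignment(6, "single_beta_other_dimer_flagged", call)
        return GroupAssignment(6, "multi_beta_with_dimer", call)

    if betas and genes - betas:
        return GroupAssignment(1, "non_complementary_mixed", call)
    if not betas:
        return GroupAssignment(2, "alpha_only", call)
    # beta genes only (and not ITGB4), no dimer possible
    return GroupAssignment(1, "beta_only_no_dimer_flagged", call)


def _expressed_integrins(
    matrix: CountMatrix, cell_row: int, integrin_cols: dict[str, int],
    threshold: int,
) -> set[str]:
    row = matrix.counts.getrow(cell_row)
    present = set()
    cols = dict(zip(row.indices, row.data))
    for gene, j in integrin_cols.items():
        if cols.get(j, 0) >= threshold:
            present.add(gene)
    return present


def classify_all(
    matrix: CountMatrix,
    ctc_mask: np.ndarray,
    table: PairingTable | None = None,
    positivity_threshold: int = 1,
) -> tuple[pd.DataFrame, GroupSummary]:
    """Classify every CTC in the matrix from its expressed integrin genes.

    Parameters
    ----------
    matrix : full count matrix.
    ctc_mask : boolean mask over cells marking CTCs.
    table : pairing table (canonical by default).
    positivity_threshold : minimum raw count for an integrin gene to be
        considered expressed (same convention as marker positivity).

    Returns
    -------
    (labels, summary) where ``labels`` is a DataFrame indexed by barcode
    with columns ``group_id``, ``rule_fired``, ``n_dimers``, ``dimers``
    (semicolon-joined ``ITGA6:ITGB4`` tokens) and ``unpaired``, one row per
    CTC in matrix order.
    """
    ctc_mask = np.asarray(ctc_mask, dtype=bool)
    if ctc_mask.sum() == 0:
        raise ValueError("ctc_mask flags no cells")
    if table is None:
        table = build_pairing_table()

    integrin_cols = {
        g: matrix.gene_index(g)
        for g in matrix.gene_symbols
        if g.upper() in SUBUNIT_SHORT_NAMES
    }
    rows = []
    assignments: list[GroupAssignment] = []
    for i in np.flatnonzero(ctc_mask):
        expressed = _expressed_integrins(
            matrix, int(i), integrin_cols, positivity_threshold
        )
        a = assign_group(expressed, table)
        assignments.append(a)
        rows.append(
            {
                "barcode": matrix.barcodes[int(i)],
                "group_id": a.group_id,
                "rule_fired": a.rule_fired,
                "n_dimers": a.heterodimer_call.n_dimers,
                "dimers": ";".join(
                    f"{x}:{y}" for x, y in sorted(a.heterodimer_call.dimers)
                ),
                "unpaired": ";".join(sorted(a.heterodimer_call.unpaired)),
            }
        )
    labels = pd.DataFrame(rows).set_index("barcode")
    summary = summarize_heterodimer_counts(
        labels["group_id"].tolist(), [a.heterodimer_call for a in assignments],
        rules=labels["rule_fired"].tolist(),
    )
    return labels, summary


def summarize_heterodimer_counts(
    labels: Sequence[int],
    calls: Sequence[HeterodimerCall],
    rules: Sequence[str] | None = None,
) -> GroupSummary:
    """Summarise per-cell dimer counts over aligned labels and calls."""
    if len(labels) != len(calls):
        raise ValueError("labels and calls must be aligned")
    labels = list(labels)
    dimer_counts = [c.n_dimers for c in calls]
    group_sizes = {g: 0 for g in GROUP_IDS}
    per_max: dict[int, int] = {}
    per_min: dict[int, int] = {}
    for g, n in zip(labels, dimer_counts):
        group_sizes[g] += 1
        per_max[g] = max(per_max.get(g, n), n)
        per_min[g] = min(per_min.get(g, n), n)
    n_multi = sum(
        1 for g, n in zip(labels, dimer_counts) if g != 8 and n >= 3
    )
    n_cells = len(labels)
    capable = sum(group_sizes[g] for g in (3, 4, 5, 6, 7, 8))
    flagged: dict[str, int] = {}
    if rules is not None:
        for r in rules:
            if r.endswith("_flagged"):
                flagged[r] = flagged.get(r, 0) + 1
    return GroupSummary(
        group_sizes=group_sizes,
        dimer_counts=dimer_counts,
        per_group_max_dimers=per_max,
        per_group_min_dimers=per_min,
        n_multi_dimer_outside_b4_group=n_multi,
        n_cells=n_cells,
        heterodimer_capable_fraction=capable / n_cells if n_cells else 0.0,
        flagged_rules=flagged,
    )


def write_assignments(
    labels: pd.DataFrame, summary: GroupSummary, outdir: str | Path
) -> None:
    """Write per-cell assignments (TSV) and the group summary (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels.to_csv(outdir / "group_assignments.tsv", sep="\t")
    with open(outdir / "group_summary.json", "w") as fh:
        json.dump(summary.as_dict(), fh, indent=2, sort_keys=True)
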