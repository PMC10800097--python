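# ctcintegrins

Integrin-profile classification and functional profiling of circulating
tumor cells (CTCs) from single-cell RNA-seq count matrices.

## The problem

CTCs survive in the bloodstream without contact to the basal membrane or
extracellular matrix, and integrins — heterodimeric adhesion receptors
assembled from one α and one β subunit — are central to that
anchorage-independent survival. The human repertoire of 18 α and 8 β
subunit genes assembles into exactly 24 permitted αβ heterodimers; which
of those a CTC could form is readable from its transcriptome, because a
*potential* heterodimer only requires co-expression of two complementary
subunit genes. The laminin receptor α6β4 (ITGA6 + ITGB4) is of particular
interest: cells carrying it can synthesise their own laminin ligands and
thereby mimic basal-membrane attachment.

This package implements, as a tested and reusable pipeline for analysts
working with CD45-depleted single-cell data:

1. **QC filtering** of barcodes by total UMIs, detected genes and
   mitochondrial UMI fraction.
2. **CTC identification** — a cell is a CTC iff at least one epithelial
   marker gene (KRT5/7/8/14/18, EPCAM, MUC1, CDH1) has a raw count ≥ 1
   (threshold configurable).
3. **Heterodimer inference** — for a cell expressing subunit set *S*, the
   potential dimers are `{(α,β) ∈ P : α ∈ S, β ∈ S}` with *P* the canonical
   24-pair table (β1 pairs α1–α11 and αV; β2 pairs αL/αM/αX/αD; β3 pairs
   αIIb/αV; β4 pairs α6; β5/β6/β8 pair αV; β7 pairs α4/αE).
4. **Nine-group classification** by a fixed decision tree: no integrin
   genes → 9; ITGA6+ITGB4 → 8; ITGB4 alone → 7; otherwise, with ≥ 1
   inferred dimer, a single β gene maps β1/β2/β3 to groups 3/4/5 and
   multiple β genes to group 6; with no dimer, α-only → 2, else → 1.
5. **Functional profiling** — per-group expressing-cell fractions of a
   36-gene tumor-progression panel (stemness, EMT, laminins, invasion,
   chemokines/cytokines, epithelial identity, proliferation); two-sided
   Fisher exact tests of each group against the no-integrin group with
   Benjamini–Hochberg correction; Wilcoxon rank-sum differential
   expression on log-normalised counts; upper-tail hypergeometric
   gene-set overlap against GMT gene sets,
   `p = P(X ≥ k), X ~ Hypergeom(N, K, n)`.
6. **Synthetic cohorts** — a deterministic 445-CTC census fixture (group
   sizes 143/81/8/2/11/38/3/5/154 over groups 1–9, embedded in 1,000
   marker-negative background cells) and stochastic cohorts with planted
   per-group Bernoulli panel rates and negative-binomial counts, so the
   whole pipeline is testable without any data download.

## Worked example

```bash
ctcintegrins fixture --outdir fixture10x --seed 0
ctcintegrins run --matrix fixture10x --outdir out
```

prints

```
group sizes: 1:143, 2:81, 3:8, 4:2, 5:11, 6:38, 7:3, 8:5, 9:154
significant genes vs reference: {"1": "0/36", ..., "8": "0/36"}
```

i.e. of the 445 CTCs, 154 express no integrin gene (group 9), 224 express
only non-complementary subunits or α subunits alone (groups 1–2), and 67
cells (15 %) could assemble at least one heterodimer — 5 of them
co-expressing ITGA6 and ITGB4 (group 8). In the deterministic fixture the
panel genes carry no planted group effects, so no gene is significant.
The same from Python, plus the per-cell dimer calls:

```python
from ctcintegrins import (build_fixture, identify_ctcs, classify_all,
                          infer_heterodimers)

matrix, truth = build_fixture(seed=0)
mask, report = identify_ctcs(matrix)      # report.n_ctc -> 445
labels, summary = classify_all(matrix, mask)
summary.group_sizes                        # {1: 143, 2: 81, ..., 9: 154}
summary.per_group_max_dimers[8]            # 7
call = infer_heterodimers({"ITGB4", "ITGB1", "ITGA6"})
sorted(call.dimer_names())                 # ['a6b1', 'a6b4']
```

On a stochastic cohort with planted effects (500 cells per group, 26
panel genes elevated from a 2 % baseline to 40 % positivity in group 8):

```python
from ctcintegrins import (generate_cohort, panel_frequencies,
                          compare_vs_reference)
from ctcintegrins.functional_profiling import significant_counts

m, truth = generate_cohort(seed=0)
labels = truth.loc[truth.is_ctc, "true_group"].rename("group_id")
tests = compare_vs_reference(panel_frequencies(m, labels))
significant_counts(tests)[8]               # '26/36'
```

## Layout

- `src/ctcintegrins/integrin_knowledge.py` — subunit vocabulary, pairing
  table (also bundled as `data/integrin_pairs.tsv`), heterodimer inference
- `src/ctcintegrins/matrix.py` — sparse cells×genes container, 10x trio
  and dense-CSV I/O
- `src/ctcintegrins/ctc_identification.py` — QC and marker-based calling
- `src/ctcintegrins/group_classifier.py` — nine-group decision tree and
  cohort summaries
- `src/ctcintegrins/functional_profiling.py` — panel frequencies, Fisher/
  BH, rank-sum DE, hypergeometric overlap, GMT parsing
- `src/ctcintegrins/synthetic_cohort.py` — census fixture and stochastic
  cohort generators
- `src/ctcintegrins/workflow_io.py`, `cli.py` — pipeline orchestration,
  YAML config and the `ctcintegrins` command

See `docs/methods.md` for the modelling choices, defaults and known
limitations.
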