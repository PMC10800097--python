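# Methods

## Potential-heterodimer model

A heterodimer call is purely transcriptional: a cell "potentially
expresses" integrin αβ when both subunit genes are positive, positivity
being a raw count at or above a configurable threshold (default 1). No
activation state, ligand binding, translation efficiency or protein-level
assembly is modelled; the call is an upper bound on what the cell could
assemble. The pairing repertoire is the canonical 24-pair human table
(β1: α1–α11 + αV; β2: αL, αM, αX, αD; β3: αIIb, αV; β4: α6; β5/β6/β8: αV;
β7: α4, αE), bundled as `data/integrin_pairs.tsv` and replaceable at run
time for non-human or customised repertoires. One subunit may participate
in several dimers simultaneously (β1 with several α partners, αV with
several β partners); the inference is therefore monotone — adding an
expressed subunit can only add dimers.

Gene symbols are matched case-insensitively (`ITGA2b` → `ITGA2B`), since
mixed-case variants of the αIIb symbol are common in the wild. All 26
subunit genes are accepted even though only 14 occur in the bundled
census fixture.

## Nine-group classification

The decision tree runs in a fixed order: empty set → group 9; ITGA6 and
ITGB4 both present → group 8; ITGB4 present → group 7; otherwise dimers
are inferred, and with at least one dimer a single β gene maps
β1/β2/β3 → groups 3/4/5 while two or more β genes map to group 6; with no
dimer, α-only cells are group 2 and everything else group 1. β4 status is
checked *before* the dimer logic because the α6β4 axis is the focal
biology: a cell carrying ITGB4 plus an unrelated α4β1 pair is group 7,
not group 6.

Two inputs have no conventional home and are assigned with an explicit
flag in `rule_fired`: a cell whose only β subunit is β5/β6/β7/β8 but
which still forms a dimer (αVβ5 alone, say) goes to group 6
(`single_beta_other_dimer_flagged`), and a cell expressing only β genes
(other than β4) with no possible dimer goes to group 1
(`beta_only_no_dimer_flagged`). Neither pattern occurs in the census
fixture; the flags make them auditable if they occur in real data.

The cohort summary reports per-group sizes, per-cell dimer counts,
per-group min/max, the heterodimer-capable fraction (groups 3–8), and the
number of cells outside group 8 with ≥ 3 dimers. In the bundled census
fixture that last count is 2: one eight-gene combination pairs three α
partners onto β1, and one combination co-expresses αV with both β1 and
β3, which under the repertoire necessarily yields αVβ1 and αVβ3 alongside
α2bβ3. Group-8 cells carry 3–7 potential dimers each (sorted counts
{3, 5, 5, 5, 7}).

## QC and CTC identification

QC retains barcodes with total UMIs ≥ `min_umi` (default 500), detected
genes ≥ `min_genes` (default 200) and mitochondrial UMI fraction ≤
`max_mito_fraction` (default 0.20, genes matched by the `MT-` prefix).
The defaults are conventional 10x starting points; appropriate values are
dataset-dependent, which is why they live in the run configuration and
the removal fraction is always reported rather than targeted.

A CTC is any cell with at least one positive epithelial marker among
KRT5, KRT7, KRT8, KRT14, KRT18, EPCAM, MUC1 and CDH1. EPCAM-negative
keratin-positive cells are deliberately included — EPCAM-low CTCs are
frequent. CD45 depletion is assumed to have happened upstream
(experimentally); an optional `exclude_ptprc_positive` switch drops
PTPRC-positive cells for partially depleted inputs, off by default.

## Frequency profiling and statistics

Functional potential is profiled as the fraction of cells per group with
positive expression of each gene in a 36-gene tumor-progression panel
(stemness 6, EMT 9, laminins 5, invasion 6, chemokine/cytokine 4,
epithelial 5, proliferation 1; fully replaceable via a two-column TSV).
Presence/absence rather than mean expression is used because for
shallow scRNA-seq of rare cells the positivity call is the robust signal
and there is no linear map from transcript level to functional protein.

Each group is compared to the no-integrin reference group (9) per gene
with a **two-sided Fisher exact test** on the 2×2 expressing table,
BH-corrected within each group across its panel (significance at
q < α, default α = 0.05); a chi-square variant is available via
`method="chi2"`. Fisher + BH is this package's choice for small-group
binary frequencies; nothing fancier is warranted at n as small as 2
cells per group. Empty groups are flagged untestable, never imputed.

Differential expression uses per-cell normalisation to 10,000 counts,
log1p, a two-sided Mann–Whitney rank-sum test per gene, BH across the
tested universe, and reports the top-n (default 50) genes with an
up/down direction from the mean difference. Constant genes get p = 1 by
convention (the tie-corrected statistic is undefined). Ties in adjusted p
are broken by raw p and then by absolute mean difference, with a stable
sort, so rankings are reproducible.

Gene-set overlap is the MSigDB-style upper-tail hypergeometric
computation: p = P(X ≥ k), X ~ Hypergeom(N, K, n) with N the universe
size (default: genes detected in the matrix; overridable to a fixed
integer to mimic a database-defined universe), K the set size, n the
query size, k the overlap. Gene sets are read from GMT. No running-sum
permutation GSEA is provided — overlap enrichment is the intended scope.

The statistical engines are scipy/statsmodels
(`fisher_exact`, `hypergeom.sf`, `multipletests(fdr_bh)`,
`mannwhitneyu`); the test suite cross-checks them against independent
brute-force oracles (exhaustive fixed-margin enumeration for every 2×2
table with margins ≤ 12, direct PMF summation for universes ≤ 50, and a
literal BH step-up).

## Synthetic data

The generators define the study conditions; they are not tuning knobs.

**Census fixture** (`build_fixture`): 445 CTCs with group sizes
143/81/8/2/11/38/3/5/154, plus 1,000 marker-negative background cells.
Heterodimer-capable cells (groups 3–8, 67 cells) get exactly the
per-combination subunit sets of the emulated census, at count 1 — the
downstream analysis is set-based, so unit counts exercise it fully. One
census combination is emitted with a documented correction (ITGA2B in
place of a printed ITGA2 that cannot partner β3). Group-1 and group-2
cells draw from fixed, explicitly listed pattern pools (validated at
construction: group-1 patterns mix chains, contain no β4 and can form no
dimer; group-2 patterns are α-only) rather than rejection sampling, so
the fixture stays deterministic and auditable. Every CTC receives one
cycling keratin/MUC1/CDH1 marker; EPCAM positivity is planted in
round(0.026 × 445) = 12 cells (whole-cell rounding of a 2.6 % positive
fraction, i.e. 97.3 % EPCAM-negative) and MKI67 in round(0.0088 × 445) =
4 cells. All 14 observed subunit genes appear in at least one CTC.

**Stochastic cohorts** (`generate_cohort`): default 500 cells in each of
the nine groups. Integrin patterns are resampled from the census
combinations (weighted by their census multiplicities) and the group-1/2
pools. Panel genes are Bernoulli-positive at a 0.02 baseline everywhere,
with 26 designated genes (the stemness, EMT, laminin and invasion
categories) elevated to 0.4 in the α6β4 group; 13 additional planted DE
genes outside the panel are positive at 0.6 with negative-binomial mean 8
in group 8 versus 0.05/mean 3 elsewhere (the fourteenth planted DE gene,
VIM, sits inside the panel and inherits the panel effect). Positive genes
draw NB(mean 3, dispersion 0.5) counts floored at 1; negative genes are
0. The per-group rates are explicit stand-ins chosen to give the Fisher
route near-certain power at n = 500 — they are generator parameters, not
measured biology, and notably include EPCAM among the elevated EMT genes
even though real α6β4 CTC populations are predominantly EPCAM-negative.

Every cell in both generators also carries a seeded Poisson null
transcriptome (240 synthetic `GENEnnnn` genes at mean 3, ≈ 720 UMIs and
≈ 228 detected genes per cell) and three `MT-` genes at mean 25 (≈ 9 %
mitochondrial fraction), so default QC thresholds and the DE null
universe are exercised meaningfully. What the generators do **not**
emulate: transcriptome-wide expression structure, library-size variation
beyond the NB counts, dropout curves, doublets, ambient RNA or batch
effects — passing tests demonstrate correctness of the pipeline's logic
and statistics under the stated generative model, not performance on real
sequencing artefacts.

All randomness flows from a single `numpy.random.default_rng(seed)`;
identical seeds give byte-identical written outputs.

## Numerical and I/O choices

Counts are integer and sparse end-to-end (MatrixMarket coordinate format
with 1-based indices in the 10x trio, genes × cells on disk as 10x
writes it, cells × genes in memory). Frequencies are exact rational
fractions of group size; no pseudocounts are added anywhere. Fisher
tests use the exact conditional distribution, not asymptotics. In
`classify_all`, permuting cells or genes never changes any assignment
(set-based rules), which the suite checks by property.

## Known limitations

- Potential heterodimers over-count: co-expression does not guarantee
  assembly.
- The positivity threshold conflates biological absence with dropout; at
  scRNA-seq depths typical for rare cells the panel fractions are lower
  bounds.
- The nine-group scheme is set-based by design; no expression-weighted or
  probabilistic grouping is offered.
- The census-derived fixture reflects one cohort's combination spectrum;
  the stochastic cohort's panel rates are synthetic stand-ins.
- Problem sizes in the test suite (445 + 1,000 fixture cells, 4,500
  cohort cells, 20-seed power sweeps at 1,000 cells) were chosen to make
  every statistical check decisive at desk scale.
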