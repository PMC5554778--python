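# Methods

This note documents the models, parameter choices, and numerical
conventions behind `periblast`, and what the synthetic-data tests do and
do not demonstrate about real data.

## The noise statistic

Transcriptional noise is quantified within a homogeneous population as
the distribution of pairwise cell–cell distances d = (1 − ρ)/2, with ρ
the Spearman rank correlation over a gene set. Implementation: expression
values are converted to mid-ranks per cell (ties get average ranks, the
standard convention) and the full correlation matrix is computed as the
Pearson correlation of the rank vectors, which is exactly Spearman's ρ;
d is clipped into [0, 1] against floating-point round-off. A unit test
checks the vectorized matrix against a per-pair `scipy.stats.spearmanr`
loop at 1e-12. Cells with zero variance across the gene set have no
defined ranks; their pairs are dropped with a warning.

The gene set is the population's **top-500 HVGs**, selected per group:
CV² = Var/mean² of CPM values per gene, a centered rolling median of CV²
over genes sorted by (mean, gene id) as the trend, and the arithmetic
residual CV² − trend as the variability score. Design choices where the
procedure is genuinely open:

* **Residual, not ratio.** The distance to the trend is the signed
  arithmetic residual; it preserves direction and is the minimal reading
  of "distance to rolling median".
* **Window 101 genes**, shrinking at the edges (`min_periods=1`). No
  window is canonical; 101 smooths trends over the few-thousand-gene
  matrices this package targets and is a config key (`hvg.window`).
* **Mean floor**: genes with mean raw count < 10 are excluded before
  trend fitting and ranking (`hvg.min_mean_counts`); the floor can be
  applied on a different scale by passing `filter_means`.
* **Ties** in the variability score are broken by gene id so selection
  is deterministic.

Group comparisons: the **rank-sum test** treats the two pairwise-d
vectors as independent samples. Pairs sharing a cell are not
independent; the test is kept because it is the field's convention, and
a **permutation test** is provided as the dependence-respecting
alternative: cell group labels (never pair labels) are re-assigned B
times (default 1,000, seeded) and the difference of median within-group
d is recomputed. For speed the permutation statistic is computed on the
union of the two groups' HVG sets with the full d matrix built once;
re-selecting HVGs inside every permutation would multiply the cost by B
for a second-order effect on the null. p uses the add-one estimator
(1 + #extreme)/(1 + B), so the smallest attainable p is 1/(B+1).
Calibration is verified by simulation: under identical groups the
rejection rate at 0.05 stays within [0.01, 0.10] over 200 seeds.

## Normalization

Counts per million of mapped reads per cell. Two denominator policies:
`autosomes_only` (the default for expression analyses; X, Y and
mitochondrial genes are still reported, scaled by the autosomal total)
and `all_chromosomes` (used for all X-dosage quantities). Cells with a
zero denominator are flagged and zeroed rather than dropped.

## Quality control

Strict boundary semantics, verbatim from the filtering rules: fail iff
genes detected < 4,000 (detection = count ≥ 1, the minimal reading — no
higher detection threshold is implied by the rule), fail iff
mitochondrial fraction > 0.10 (computed on raw counts, before
normalization), trophoblast iff all three of *Elf5*, *Wnt7b*, *Tex19.1*
have count > 1. Multiplicity (single/doublet/triplet/multiple/empty)
comes from well annotation, as picked; triplets, multiples and empties
are removed, doublets kept by default (`qc.drop_doublets` to exclude).
The filter is idempotent and reports a verdict row for every input
cell. Note the 4,000-gene rule presumes a full transcriptome; on
desk-scale synthetic matrices the threshold must be scaled to the gene
count (the demo uses 800 of 2,000 genes).

## X chromosome

Sex per embryo: female iff the summed Y-gene counts over the embryo's
cells < 10. Dosage ratio per stage × chromosome: female median over male
median of per-cell summed chromosome CPM (all-chromosome policy). The
per-cell X proportion uses X/(X + rest) — bounded by 1 — with the
X/non-X ratio available as an option, since "relative to all other
chromosomes" is ambiguous between the two.

The regulator screen correlates each gene's CPM with the per-cell summed
X CPM (Spearman; t-approximation p-values, switching to a seeded
Monte-Carlo permutation p below 10 cells where the approximation is
poor; full enumeration would add nothing at those sizes). Genes enter
the screen at mean raw count > 1 — a CPM threshold of 1 would be
vacuous, so the count scale is the sensible reading. p-values are BH
adjusted; results are ranked by |ρ|. The default population is female
cells of the embryonic lineage at one stage (reactivation and
inactivation are female phenomena); an all-cells mode exists for
sensitivity analysis. X-linked genes stay eligible but are flagged:
they are components of the covariate, so their correlations are partly
self-correlation. Recovery tests therefore count planted regulators
against the non-X-linked pool.

Note the female/male X ratio is slightly compressed below the true
dosage multiplier under all-chromosome CPM: the female X inflates the
female library total, deflating all female CPM values by the X share of
the library (~5% here). This is a property of the estimator, not a bug,
and stays well inside the ±15% recovery band.

## Lineage analysis

The DE step deriving lineage sets is a deliberate rank-based stand-in
honoring the fold-change/FDR thresholds (adjusted p ≤ 0.05, |log2 FC of
CPM means, pseudocount 1| > 2): a per-gene two-sided rank-sum test with
BH adjustment. A negative-binomial GLM with shrinkage would be the
heavyweight alternative; the stand-in's recovery is verified directly on
planted programs (≥ 90% recovery, ≤ 2% cross-assignment at 26 cells per
lineage and 8-fold programs), and externally derived gene sets can be
supplied to bypass it entirely.

Wave labels: a lineage gene is **early** if detected in > 25% of
uncommitted-stage cells, **late** otherwise (`lineage.early_detect_frac`;
the early/late distinction is descriptive in the source literature, so
the threshold is an explicit package convention).

The per-cell **lineage ratio** n_epi/(n_epi + n_pre) counts detected
(count ≥ 1) set genes, so it is invariant to normalization; cells
detecting neither set are flagged undefined. Committed-stage cells with
ratio in [0.3, 0.7] are flagged "intermediate" (band configurable) for
exclusion from downstream noise groups. The **driver screen** is the
same Spearman/BH machinery against the ratio; genes that are themselves
set members are flagged circular and recovery is assessed outside them.

Quadrant assignment scores each cell against user-supplied reference
profiles (genes × quadrants) by Spearman correlation over shared genes
(≥ 50 required) and takes the argmax, flagging exact ties and
degenerate (constant) cells. The mapping procedure is a reconstruction;
the reference dataset itself is out of scope.

## Bivalency

Per region, log2((K4 + ε)/(K27 + ε)) with ε = 1 in score units
(zero-coverage regions would otherwise be undefined; ε rescaling
preserves the rank order of positive-score regions). Regions are first
restricted to K4-bound sites (score above `k4_min`, default 0). Early
and late regions are distinct sites, i.e. unpaired, so the default test
is the two-sample rank-sum; a signed-rank variant exists for explicitly
matched region tables but pairs in label order with truncation and warns
accordingly. Mark-swap antisymmetry (swapping the two score columns
negates every log ratio and flips the direction) holds exactly and is
tested.

## The synthetic-data generator

Counts are negative binomial, parameterized mean/dispersion with
Var = μ + φμ² and sampled as gamma–Poisson, so φ moves CV²
(CV² = 1/μ + φ) independently of the mean — the property the noise
analyses need. On top of gene baseline means (log-uniform in
`nb_mean_range`) the generator composes, per cell: a lognormal library
factor (σ = 0.3, so CPM is non-trivial); an X-activity factor =
stage-and-sex dosage multiplier × lognormal jitter (σ = 0.2) applied to
X-linked genes; Y-linked genes silenced in females; a cell-cycle phase
drawn from the group's (G1, S, G2M) simplex boosting that phase's
signature genes ×4; lineage programs (below); regulator genes whose
means couple to the X-activity jitter with alternating sign (effect
2.0 on the log scale); and group-specific dispersion.

Default group sizes follow the study populations the analyses target
(99 uncommitted ICM, 26 committed epiblast, 26 PrE, 260 post-implantation
epiblast, 120 uncommitted late epiblast, 23 primitive streak).
Dispersions per group are free parameters — no quantitative noise levels
exist to emulate — so the defaults encode only the expected ordering
(uncommitted noisy, streak quietest) and only orderings, never
magnitudes, are asserted anywhere.

**Lineage programs.** Each side has planted genes with off-means
log-uniform in (0.2, 1.0) and on-state = 8 × off. Committed cells
express their own side's genes in the on state and the other side at
baseline leak. At the uncommitted stage each cell carries a latent
lineage-bias logit u ~ N(0, 0.5); early-wave genes turn on per cell ×
gene with probability sigmoid(logit(0.3) ± u) (salt-and-pepper
co-expression, odds tilted by the bias), late-wave genes are silenced
(×0.02). Planted **driver genes** couple to u with alternating sign —
the latent bias is what makes "genes correlated with the lineage ratio"
a recoverable planted truth rather than pure sampling noise.

**Embryos and sexes.** Cells are distributed round-robin over embryos
(default 4 per group); embryo sexes are Bernoulli(frac_female) unless
overridden, with one embryo flipped if a ≥2-embryo stage comes out
single-sex — the emulated study design has embryos of both sexes at
every stage.

**Contaminants**, appended with recorded classes: low-complexity cells
(80% of genes zeroed), high-mitochondrial cells (mito load doubled until
it exceeds 10% of the library — the violation is guaranteed by
construction), trophoblast-like cells (all three markers ≥ 2 by
construction), doublets (sum of two same-group cells, multiplicity
annotated), and empty wells (means ×10⁻³).

**Chromatin fixtures**: one region per gene; K4 = L√r·ε₄,
K27 = (L/√r)·ε₂₇ with independent lognormal noise (log-sd σ), so the
expected log2 ratio equals log2 r exactly and σ = 0 degenerates to the
configured ratio.

Determinism: a single `numpy` Generator seeded from the config drives
every draw in fixed order; identical config (including seed) reproduces
the matrix bit-exactly, which the pipeline inherits (same seed →
byte-identical summary JSON).

## What the synthetic tests do and do not show

The generator emulates the statistical skeleton the methods assume:
overdispersed counts, library-size variation, dosage structure, program
exclusivity, planted correlations. It does **not** simulate reads,
UMIs, mapping artifacts, batch effects (the batch column is plumbing; a
ComBat-style correction is an interface hook only), ambient RNA,
transcript-length effects, or spatial structure. Passing tests
demonstrate that the statistics recover planted effects of realistic
magnitude at study-scale sample sizes and that null calibrations hold —
not that any particular biological dataset will show those effects.

## Problem sizes and numerical conventions

Simulation studies run at desk scale by design: 600–2,000 genes,
26–100 cells per group, 100 replicate seeds for recovery rates (200 for
null calibration), 1,000 permutations per test. The full test suite
runs in about a minute; `scripts/acceptance.py` in about one minute.
Degenerate inputs are contracts, not crashes: zero-denominator cells are
flagged, constant cells/ genes give NaN correlations and are excluded
with warnings, empty matrices round-trip, and configuration errors name
the offending field.

## Known limitations

* The rank-sum comparison of pairwise distances inherits the pair
  dependence problem; use the permutation test when calibration matters.
* The DE stand-in has no dispersion shrinkage; at very small n it is
  conservative relative to NB-GLM methods.
* The X screen's covariate includes the measured gene itself for
  X-linked genes (flagged, not removed).
* CPM-based dosage ratios are compressed by the denominator coupling
  described above.
* Spearman p-values use the t approximation except at n < 10
  (Monte-Carlo permutation); at moderate n with heavy ties the
  approximation is slightly anticonservative.
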