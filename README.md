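# periblast

Single-cell RNA-seq analytics for peri-implantation mouse embryos
(E3.5–E6.5): quality filtering, autosome-denominated CPM normalization,
highly variable gene (HVG) selection, a pairwise-correlation measure of
**transcriptional noise**, X-chromosome reactivation/inactivation dosage
analysis with a regulator screen, epiblast/primitive-endoderm (PrE)
lineage symmetry-breaking scores, and H3K4me3/H3K27me3 bivalency ratios.
A synthetic-data generator with fully recorded ground truth makes every
stage testable offline, with no download.

**Who it is for.** Developmental and single-cell biologists who want the
bespoke statistics of peri-implantation embryo studies — not the generic
clustering toolbox — as tested, reusable library functions with a thin
CLI.

## The statistics at the core

* **Transcriptional noise.** Within a homogeneous cell population,
  every unordered pair of cells (i, j) is scored by

  d(i, j) = (1 − ρ(i, j)) / 2,

  where ρ is Spearman's rank correlation across the population's top-500
  HVGs. d ∈ [0, 1]; noisier populations are more dispersed in expression
  space and shift the whole d distribution upward. Groups are compared
  by the rank-sum test on pooled pairwise distances and by a permutation
  test that re-assigns *cell* labels (respecting the dependence between
  pairs that share a cell).
* **HVG selection.** Per gene, CV² = Var/mean² of CPM expression; the
  variability score is the distance of CV² from a running median of CV²
  over genes ordered by mean, after excluding genes below a mean of ten
  raw counts.
* **QC.** Cells are removed when annotated as triplet/multiple/empty,
  when expressing fewer than 4,000 genes, when >10% of counts are
  mitochondrial, or when all three trophoblast markers (*Elf5*, *Wnt7b*,
  *Tex19.1*) exceed one count. Doublets are kept by default.
* **X dosage.** Embryos with a summed Y-gene count below ten are female.
  Female/male dosage is the ratio of sex-wise medians of per-cell
  chromosome expression (all-chromosome CPM); the regulator screen
  correlates every expressed gene with per-cell total X expression
  (Spearman, Benjamini–Hochberg FDR).
* **Lineage symmetry breaking.** Lineage gene sets come from a
  rank-based DE screen between committed epiblast and PrE (adjusted
  p ≤ 0.05 and |log2 FC| > 2); each cell's lineage ratio is
  n_epi / (n_epi + n_pre) over *detected* set genes. Candidate drivers
  are genes correlated with the ratio across uncommitted cells.
* **Bivalency.** Per gene-associated region, log2((K4+ε)/(K27+ε));
  early-wave lineage genes are compared to late-wave genes.

## Worked example

The bundled demo simulates an embryo series (99 E3.5 ICM cells, 26+26
committed E4.5 epiblast/PrE, 260 E5.5 epiblast, 120 E6.5 epiblast, 23
E6.5 primitive-streak cells, plus planted contaminants) and runs every
stage:

```sh
periblast run-all --demo --out demo_out --seed 1
```

or in Python:

```python
import periblast as pb
summary = pb.run_pipeline(pb.demo_config(seed=1, out_dir="demo_out"))
```

With seed 1 this prints (in `demo_out/summary.json`):

```
n_cells_input           586
n_cells_pass_qc         564          # the 22 planted contaminants removed
noise_median_d_by_group E3.5 0.397 | E4.5:epi 0.333 | E5.5 0.291
                        E6.5:epi 0.366 | E6.5:ps 0.209
x_dosage_ratio_by_stage E3.5 1.38 | E4.5 2.22 | E5.5 1.67 | E6.5 1.08
n_epiblast_genes 50     n_pre_genes 52
lineage_ratio_abs_dev_median  uncommitted 0.056 | committed 0.203
bivalency  early median log2(K4/K27) 2.02 vs late −1.13 (p ≈ 3e-17)
```

Reading this: noise is highest in the uncommitted ICM (E3.5) and the
uncommitted E6.5 epiblast and collapses in the primitive streak; the
female/male X ratio rises toward 2 at reactivation and returns to ~1 as
inactivation completes; committed-stage cells sit near lineage-ratio 0
or 1 (|ratio − 0.5| ≈ 0.2) while uncommitted cells co-express both
programs (≈ 0.06); early-wave lineage genes are K4-dominated, late-wave
genes K27-dominated. All of these mirror the planted structure of the
simulation, whose every effect is recorded in the returned
`GroundTruth`.

Per-stage subcommands (`periblast simulate / qc / noise / xchrom /
lineage / bivalency`) operate on saved MTX + TSV fixture directories;
see `periblast --help`.

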