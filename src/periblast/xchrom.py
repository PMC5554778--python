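"""X-chromosome dosage analysis.

Sex is assigned per embryo from the summed Y-gene counts (fewer than ten
counts across the embryo's cells means female).  Female/male dosage is
the ratio of sex-wise medians of per-cell summed chromosome expression
(all-chromosome CPM normalization), computed per stage for the X and any
reference autosomes.  The per-cell X proportion is the fraction of raw
counts on the X.  The regulator screen correlates every sufficiently
expressed gene with the per-cell total X expression (Spearman, BH-FDR),
by default over female cells of the embryonic lineage at one stage —
reactivation and inactivation are female phenomena.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from ._stats import bh_adjust, spearman_vs_covariate
from .normalize import NormalizedMatrix, normalize_cpm

__all__ = ["assign_sex", "dosage_ratios", "x_proportion", "x_correlation_screen"]

_X_NAMES = {"chrX", "X"}
_Y_NAMES = {"chrY", "Y"}


def _chrom(adata: ad.AnnData) -> pd.Series:
    if "chromosome" not in adata.var.columns:
        raise ValueError("gene annotation lacks a 'chromosome' column")
    return adata.var["chromosome"].astype(str)


def _dense(X) -> np.ndarray:
    import scipy.sparse
    if scipy.sparse.issparse(X):
        return np.asarray(X.todense())
    return np.asarray(X)


def assign_sex(adata: ad.AnnData, y_genes: list[str] | None = None,
               threshold: int = 10, embryo_col: str = "embryo") -> pd.DataFrame:
    """Per-embryo sex from summed Y-linked counts (< threshold → female).

    Returns a DataFrame indexed by embryo with columns y_count_sum and
    sex; every cell of an embryo inherits its sex.
    """
    chrom = _chrom(adata)
    if y_genes is None:
        y_genes = adata.var_names[chrom.isin(_Y_NAMES)].tolist()
    if not y_genes:
        raise ValueError("no Y-linked genes in annotation")
    missing = [g for g in y_genes if g not in adata.var_names]
    if missing:
        raise KeyError(f"Y genes absent from annotation: {missing[:5]}")
    if embryo_col not in adata.obs.columns:
        raise ValueError(f"cell table lacks {embryo_col!r}")

    X = _dense(adata.X)
    ypos = [adata.var_names.get_loc(g) for g in y_genes]
    ysum = pd.Series(X[:, ypos].sum(axis=1), index=adata.obs_names)
    per_embryo = ysum.groupby(adata.obs[embryo_col].astype(str)).sum()
    out = pd.DataFrame({"y_count_sum": per_embryo.astype(int)})
    out["sex"] = np.where(out["y_count_sum"] < threshold, "female", "male")
    out.index.name = "embryo"
    return out


def cell_sexes(adata: ad.AnnData, sexes: pd.DataFrame,
               embryo_col: str = "embryo") -> pd.Series:
    """Broadcast the per-embryo assignment onto cells."""
    return adata.obs[embryo_col].astype(str).map(sexes["sex"]).rename("sex")


def dosage_ratios(adata: ad.AnnData, sexes: pd.DataFrame,
                  chromosomes: list[str] | None = None,
                  stage_col: str = "stage",
                  norm: NormalizedMatrix | None = None) -> pd.DataFrame:
    """Female/male ratio of median per-cell chromosome expression.

    Expression is summed per cell over each chromosome's genes after
    all-chromosome CPM normalization; the ratio divides the female
    median by the male median, per stage.  Rows where a sex is absent
    (or the male median is zero) are flagged undefined.
    """
    chrom = _chrom(adata)
    if chromosomes is None:
        chromosomes = ["chrX", "chr1", "chr4", "chr6"]
    if norm is None:
        norm = normalize_cpm(adata, policy="all_chromosomes")
    sex = cell_sexes(adata, sexes)
    stages = adata.obs[stage_col].astype(str)

    rows = []
    for stage in pd.unique(stages):
        in_stage = stages == stage
        for c in chromosomes:
            genes = adata.var_names[chrom == c]
            expr = norm.values.loc[in_stage.to_numpy(), genes].sum(axis=1)
            fem = expr[(sex[in_stage] == "female").to_numpy()]
            mal = expr[(sex[in_stage] == "male").to_numpy()]
            if len(fem) == 0 or len(mal) == 0 or np.median(mal) == 0:
                rows.append(dict(stage=stage, chromosome=c, ratio=np.nan,
                                 n_female=len(fem), n_male=len(mal),
                                 undefined=True))
            else:
                rows.append(dict(stage=stage, chromosome=c,
                                 ratio=float(np.median(fem) / np.median(mal)),
                                 n_female=len(fem), n_male=len(mal),
                                 undefined=False))
    return pd.DataFrame(rows)


def x_proportion(adata: ad.AnnData, denominator: str = "total") -> pd.DataFrame:
    """Per-cell X-linked fraction of raw counts.

    ``denominator="total"`` gives X / (X + rest), bounded by 1 (default);
    ``"non_x"`` gives the X / rest ratio instead.  Zero-total cells are
    flagged undefined.
    """
    chrom = _chrom(adata)
    X = _dense(adata.X).astype(float)
    x_mask = chrom.isin(_X_NAMES).to_numpy()
    x_counts = X[:, x_mask].sum(axis=1)
    total = X.sum(axis=1)
    if denominator == "total":
        denom = total
    elif denominator == "non_x":
        denom = total - x_counts
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(denom > 0, x_counts / np.maximum(denom, 1e-300), np.nan)
    return pd.DataFrame({"x_proportion": prop, "undefined": ~(denom > 0)},
                        index=adata.obs_names.copy()).rename_axis("cell_id")


def x_correlation_screen(adata: ad.AnnData, stage: str,
                         sexes: pd.DataFrame | None = None,
                         lineage: str | list[str] | None = None,
                         female_only: bool = True,
                         min_mean: float = 1.0,
                         stage_col: str = "stage",
                         lineage_col: str = "lineage",
                         pvalue_method: str = "auto",
                         seed: int = 0) -> pd.DataFrame:
    """Screen genes for Spearman correlation with total X expression.

    The per-cell covariate is the summed X-gene CPM under all-chromosome
    normalization.  Genes with mean raw count > ``min_mean`` over the
    selected cells enter the screen; p-values are BH-adjusted and rows
    sorted by |rho| (descending).  X-linked genes remain eligible; they
    contribute to the covariate, so their self-correlation is flagged in
    the ``x_linked`` column.
    """
    mask = adata.obs[stage_col].astype(str) == stage
    if lineage is not None:
        lineages = [lineage] if isinstance(lineage, str) else list(lineage)
        mask &= adata.obs[lineage_col].astype(str).isin(lineages)
    if female_only:
        if sexes is None:
            sexes = assign_sex(adata)
        mask &= (cell_sexes(adata, sexes) == "female").to_numpy()
    sub = adata[mask.to_numpy() if hasattr(mask, "to_numpy") else mask]
    if sub.n_obs < 5:
        raise ValueError(f"only {sub.n_obs} cells selected at stage {stage!r}; need >= 5")

    norm = normalize_cpm(sub, policy="all_chromosomes")
    chrom = _chrom(sub)
    x_mask = chrom.isin(_X_NAMES).to_numpy()
    covariate = norm.values.loc[:, x_mask].sum(axis=1)

    raw_means = pd.Series(_dense(sub.X).mean(axis=0), index=sub.var_names)
    genes = raw_means.index[raw_means > min_mean]
    if len(genes) == 0:
        raise ValueError("no genes pass the mean-expression filter")

    res = spearman_vs_covariate(norm.values[genes], covariate,
                                pvalue_method=pvalue_method, seed=seed)
    res["adjusted_p"] = bh_adjust(res["p_value"])
    res["x_linked"] = pd.Series(x_mask, index=sub.var_names).loc[genes].to_numpy()
    res["covariate_label"] = "x_total_cpm"
    res["stage"] = stage
    res["n_cells"] = sub.n_obs
    res = res.reindex(res["rho"].abs().sort_values(ascending=False, kind="mergesort").index)
    res.index.name = "gene_id"
    return res
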