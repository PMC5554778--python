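"""Per-cell normalization and per-gene variability scoring.

Expression is normalized to counts per million of the cell's mapped
reads.  For most analyses only autosomal genes enter the denominator
(``autosomes_only``); the X-chromosome dosage analyses use every gene
(``all_chromosomes``).

Gene variability is the distance between a gene's squared coefficient of
variation (CV² = variance / mean²) and a running median of CV² taken
over genes ordered by mean expression; highly variable genes (HVGs) are
the top-ranked genes by this distance after excluding genes below a mean
expression floor (default: mean raw count of ten).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse

__all__ = ["NormalizedMatrix", "normalize_cpm", "gene_variability", "select_hvg"]

_AUTOSOMES_EXCLUDE = {"chrX", "chrY", "chrM", "chrMT", "X", "Y", "MT", "M"}


@dataclass
class NormalizedMatrix:
    """CPM-normalized expression (cells × genes) plus the denominator policy."""

    values: pd.DataFrame
    policy: str
    zero_total_cells: list[str] = field(default_factory=list)


def _dense(X) -> np.ndarray:
    if scipy.sparse.issparse(X):
        return np.asarray(X.todense())
    return np.asarray(X)


def normalize_cpm(adata: ad.AnnData, policy: str = "autosomes_only") -> NormalizedMatrix:
    """Counts per million of mapped reads per cell.

    ``autosomes_only`` restricts the denominator (and nothing else: X/Y/M
    genes are still scaled and reported) to autosomal genes;
    ``all_chromosomes`` uses the full library.  Cells with a zero
    denominator are flagged and set to zero.
    """
    if policy not in ("autosomes_only", "all_chromosomes"):
        raise ValueError(f"unknown policy {policy!r}")
    X = _dense(adata.X).astype(float)
    if (X < 0).any():
        raise ValueError("counts must be non-negative")

    if policy == "autosomes_only":
        if "chromosome" not in adata.var.columns:
            raise ValueError("autosomes_only policy requires a 'chromosome' gene column")
        denom_genes = ~adata.var["chromosome"].astype(str).isin(_AUTOSOMES_EXCLUDE)
        denom_genes = denom_genes.to_numpy()
    else:
        denom_genes = np.ones(X.shape[1], dtype=bool)

    denom = X[:, denom_genes].sum(axis=1)
    flagged = adata.obs_names[denom == 0].tolist()
    if flagged and X.shape[0]:
        warnings.warn(f"{len(flagged)} cell(s) with zero denominator set to zero",
                      stacklevel=2)
    scale = np.divide(1e6, denom, out=np.zeros_like(denom, dtype=float),
                      where=denom > 0)
    values = pd.DataFrame(X * scale[:, None], index=adata.obs_names.copy(),
                          columns=adata.var_names.copy())
    return NormalizedMatrix(values=values, policy=policy, zero_total_cells=flagged)


def gene_variability(norm: NormalizedMatrix | pd.DataFrame,
                     cells: pd.Index | list[str] | None = None,
                     min_mean: float = 10.0,
                     window: int = 101,
                     filter_means: pd.Series | None = None) -> pd.DataFrame:
    """Per-gene CV² distance to the rolling-median trend.

    Parameters
    ----------
    norm
        Normalized matrix (or a plain cells × genes DataFrame).
    cells
        Optional cell subset (>= 3 cells required).
    min_mean
        Genes whose mean falls below this floor are excluded from trend,
        distance, and ranking.  By default the floor is applied to the
        mean of the supplied values; pass ``filter_means`` (e.g. mean raw
        counts per gene) to threshold on a different scale.
    window
        Rolling-median window in mean-sorted gene order (odd, >= 3);
        shrinks at the edges; clamped with a warning if it exceeds the
        gene count.

    Returns a DataFrame indexed by gene id with columns mean, cv2,
    trend_cv2, distance, rank, included.  Ranks (1 = most variable,
    descending distance, ties broken by gene id) form a permutation of
    ``1..n_included``; excluded genes have no rank.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    if cells is not None:
        values = values.loc[list(cells)]
    if values.shape[0] < 3:
        raise ValueError(f"need >= 3 cells, got {values.shape[0]}")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    n_genes = values.shape[1]
    if window > n_genes:
        warnings.warn(f"window {window} larger than gene count {n_genes}; clamped",
                      stacklevel=2)
        window = n_genes if n_genes % 2 == 1 else n_genes - 1
        window = max(window, 3)

    mean = values.mean(axis=0)
    var = values.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv2 = pd.Series(np.where(mean > 0, var / mean**2, np.nan), index=mean.index)

    fm = filter_means if filter_means is not None else mean
    fm = fm.reindex(mean.index)
    included = (fm >= min_mean) & cv2.notna()

    out = pd.DataFrame({"mean": mean, "cv2": cv2})
    out["trend_cv2"] = np.nan
    out["distance"] = np.nan
    out["rank"] = pd.array([pd.NA] * len(out), dtype="Int64")
    out["included"] = included

    inc = out.index[included]
    if len(inc):
        inc_df = out.loc[inc].copy()
        inc_df["_gid"] = inc_df.index.astype(str)
        # Trend over genes ordered by (mean, gene id) — deterministic under ties.
        order = inc_df.sort_values(["mean", "_gid"], kind="mergesort").index
        trend = out.loc[order, "cv2"].rolling(window, center=True, min_periods=1).median()
        out.loc[order, "trend_cv2"] = trend
        out.loc[inc, "distance"] = out.loc[inc, "cv2"] - out.loc[inc, "trend_cv2"]
        inc_df["distance"] = out.loc[inc, "distance"]
        rank_order = inc_df.sort_values(["distance", "_gid"],
                                        ascending=[False, True],
                                        kind="mergesort").index
        out.loc[rank_order, "rank"] = np.arange(1, len(rank_order) + 1)
    out.index.name = "gene_id"
    return out


def select_hvg(hvg: pd.DataFrame, n: int = 500) -> list[str]:
    """Top ``n`` genes by variability rank (all included genes, with a
    warning, if fewer than ``n`` are available)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = hvg[hvg["rank"].notna()].sort_values("rank")
    if len(ranked) < n:
        warnings.warn(f"only {len(ranked)} included genes for n={n}; returning all",
                      stacklevel=2)
    return ranked.index[:n].tolist()
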