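"""Epiblast / primitive-endoderm lineage analysis.

Lineage gene sets are derived from the committed stage by a rank-based
differential-expression screen (rank-sum test per gene, BH-adjusted,
combined with a log2 fold change of CPM means with pseudocount 1); a
gene enters a set when adjusted p <= fdr and |lfc| > the threshold.
This is a deliberate rank-based stand-in honoring the study's
fold-change/FDR thresholds; externally derived gene sets can be supplied
instead.

Each cell's lineage ratio counts the detected (count >= 1) genes of each
set: ratio = n_epi / (n_epi + n_pre), in [0, 1].  Uncommitted cells
co-express both programs (ratio near 0.5); committed cells are strongly
biased toward 0 or 1.  The driver screen correlates every expressed gene
with the per-cell ratio to nominate symmetry-breaking candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, spearman_vs_covariate
from .normalize import NormalizedMatrix

__all__ = ["LineageGeneSets", "derive_lineage_sets", "label_waves",
           "lineage_ratio", "flag_intermediate", "driver_screen",
           "assign_quadrant"]


@dataclass
class LineageGeneSets:
    epiblast_genes: list[str]
    pre_genes: list[str]
    wave: dict[str, str] = field(default_factory=dict)  # gene -> early|late
    table: pd.DataFrame | None = None                    # full DE statistics

    def __post_init__(self) -> None:
        overlap = set(self.epiblast_genes) & set(self.pre_genes)
        if overlap:
            raise ValueError(f"lineage sets overlap: {sorted(overlap)[:5]}")


def _values(norm: NormalizedMatrix | pd.DataFrame) -> pd.DataFrame:
    return norm.values if isinstance(norm, NormalizedMatrix) else norm


def derive_lineage_sets(norm: NormalizedMatrix | pd.DataFrame,
                        labels: pd.Series,
                        epiblast_label: str = "epi",
                        pre_label: str = "pre",
                        lfc_threshold: float = 2.0,
                        fdr: float = 0.05,
                        uncommitted_counts: pd.DataFrame | None = None,
                        early_detect_frac: float = 0.25) -> LineageGeneSets:
    """Derive disjoint epiblast / PrE gene sets from committed-stage cells.

    ``labels`` maps the committed cells to their lineage.  When
    ``uncommitted_counts`` (raw counts of uncommitted-stage cells) is
    given, each selected gene is wave-labeled: early if detected in more
    than ``early_detect_frac`` of uncommitted cells, late otherwise.
    """
    values = _values(norm)
    labels = labels.astype(str)
    cells_epi = labels.index[labels == epiblast_label]
    cells_pre = labels.index[labels == pre_label]
    if len(cells_epi) < 3 or len(cells_pre) < 3:
        raise ValueError("both lineages need >= 3 labeled cells")

    A = values.loc[cells_epi].to_numpy(dtype=float)
    B = values.loc[cells_pre].to_numpy(dtype=float)
    # Rank-sum per gene; constant genes give p = 1.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.mannwhitneyu(A, B, axis=0, alternative="two-sided")
    p = np.where(np.isnan(p), 1.0, p)
    adj = bh_adjust(p)
    lfc = np.log2((A.mean(axis=0) + 1.0) / (B.mean(axis=0) + 1.0))

    table = pd.DataFrame({"log2_fc_epi_vs_pre": lfc, "p_value": p,
                          "adjusted_p": adj}, index=values.columns.copy())
    selected = adj <= fdr
    epi = table.index[selected & (lfc > lfc_threshold)].tolist()
    pre = table.index[selected & (lfc < -lfc_threshold)].tolist()

    wave: dict[str, str] = {}
    if uncommitted_counts is not None:
        wave = label_waves(epi + pre, uncommitted_counts, early_detect_frac)
    table.index.name = "gene_id"
    return LineageGeneSets(epiblast_genes=epi, pre_genes=pre, wave=wave,
                           table=table)


def label_waves(genes: Sequence[str], uncommitted_counts: pd.DataFrame,
                early_detect_frac: float = 0.25) -> dict[str, str]:
    """Early = detected (count >= 1) in more than ``early_detect_frac`` of
    uncommitted-stage cells; late otherwise."""
    det = (uncommitted_counts >= 1).mean(axis=0)
    out = {}
    for g in genes:
        frac = float(det.get(g, 0.0))
        out[g] = "early" if frac > early_detect_frac else "late"
    return out


def lineage_ratio(adata: ad.AnnData | pd.DataFrame,
                  sets: LineageGeneSets) -> pd.DataFrame:
    """Per-cell detected-gene counts per set and the epiblast fraction.

    Uses detection (raw count >= 1), not magnitude, so the ratio is
    invariant to normalization.  Cells detecting neither set are flagged
    undefined (ratio NaN).
    """
    if not sets.epiblast_genes and not sets.pre_genes:
        raise ValueError("lineage sets are empty")
    if isinstance(adata, ad.AnnData):
        counts = pd.DataFrame(np.asarray(adata.X), index=adata.obs_names,
                              columns=adata.var_names)
    else:
        counts = adata
    epi = [g for g in sets.epiblast_genes if g in counts.columns]
    pre = [g for g in sets.pre_genes if g in counts.columns]
    if not epi and not pre:
        raise ValueError("no lineage-set genes present in the matrix")
    n_epi = (counts[epi] >= 1).sum(axis=1) if epi else pd.Series(0, index=counts.index)
    n_pre = (counts[pre] >= 1).sum(axis=1) if pre else pd.Series(0, index=counts.index)
    total = n_epi + n_pre
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, n_epi / np.maximum(total, 1), np.nan)
    return pd.DataFrame({"n_epi_expressed": n_epi.astype(int),
                         "n_pre_expressed": n_pre.astype(int),
                         "ratio": ratio,
                         "undefined": total.to_numpy() == 0},
                        index=counts.index.copy()).rename_axis("cell_id")


def flag_intermediate(ratios: pd.DataFrame,
                      band: tuple[float, float] = (0.3, 0.7)) -> pd.Series:
    """Committed-stage cells co-expressing both programs (ratio inside the
    band) — these are excluded from downstream noise groups."""
    lo, hi = band
    r = ratios["ratio"]
    return ((r >= lo) & (r <= hi)).rename("intermediate")


def driver_screen(norm: NormalizedMatrix | pd.DataFrame,
                  ratios: pd.DataFrame,
                  sets: LineageGeneSets | None = None,
                  min_mean: float = 1.0,
                  raw_counts: pd.DataFrame | None = None,
                  pvalue_method: str = "auto",
                  seed: int = 0) -> pd.DataFrame:
    """Correlate each expressed gene with the per-cell lineage ratio.

    Candidate symmetry-breaking drivers rank high by |rho|.  Genes that
    are themselves in the lineage sets are flagged ``circular`` (the
    ratio is built from their detection).  ``min_mean`` filters on mean
    raw counts when ``raw_counts`` is given, else on the supplied values.
    """
    values = _values(norm)
    defined = ratios.index[~ratios["undefined"]]
    defined = [c for c in defined if c in values.index]
    if len(defined) < 10:
        raise ValueError(f"need >= 10 cells with a defined ratio, got {len(defined)}")
    covariate = ratios.loc[defined, "ratio"]
    if covariate.nunique() == 1:
        raise ValueError("all lineage ratios identical")

    basis = raw_counts.loc[defined] if raw_counts is not None else values.loc[defined]
    means = basis.mean(axis=0)
    genes = means.index[means > min_mean]
    res = spearman_vs_covariate(values.loc[defined, genes], covariate,
                                pvalue_method=pvalue_method, seed=seed)
    res["adjusted_p"] = bh_adjust(res["p_value"])
    in_sets = set(sets.epiblast_genes) | set(sets.pre_genes) if sets else set()
    res["circular"] = [g in in_sets for g in res.index]
    res = res.reindex(res["rho"].abs().sort_values(ascending=False, kind="mergesort").index)
    res.index.name = "gene_id"
    return res


def assign_quadrant(norm: NormalizedMatrix | pd.DataFrame,
                    reference_profiles: pd.DataFrame,
                    cells: Sequence[str] | None = None,
                    min_shared_genes: int = 50) -> pd.DataFrame:
    """Map cells to embryo quadrants by Spearman correlation with
    user-supplied reference profiles (genes × quadrants).

    Each cell is assigned the argmax-scoring quadrant; exact ties and
    cells with undefined correlations (constant across shared genes) are
    flagged.
    """
    values = _values(norm)
    if cells is not None:
        values = values.loc[list(cells)]
    shared = values.columns.intersection(reference_profiles.index)
    if len(shared) < min_shared_genes:
        raise ValueError(f"only {len(shared)} genes shared with the references; "
                         f"need >= {min_shared_genes}")
    quadrants = list(reference_profiles.columns)
    ref = stats.rankdata(reference_profiles.loc[shared, quadrants].to_numpy(), axis=0)
    sub = values[shared].to_numpy(dtype=float)
    cr = stats.rankdata(sub, axis=1)

    cr_c = cr - cr.mean(axis=1, keepdims=True)
    ref_c = ref - ref.mean(axis=0, keepdims=True)
    num = cr_c @ ref_c
    den = np.sqrt((cr_c**2).sum(axis=1, keepdims=True) * (ref_c**2).sum(axis=0, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(den > 0, num / den, np.nan)

    rows = []
    for i, cell in enumerate(values.index):
        s = scores[i]
        if np.isnan(s).all():
            rows.append(dict(cell_id=cell, quadrant="", tie=False, undefined=True,
                             **{f"score_{q}": np.nan for q in quadrants}))
            continue
        best = np.nanmax(s)
        winners = [q for q, v in zip(quadrants, s) if v == best]
        rows.append(dict(cell_id=cell, quadrant=winners[0],
                         tie=len(winners) > 1, undefined=False,
                         **{f"score_{q}": float(v) for q, v in zip(quadrants, s)}))
    return pd.DataFrame(rows).set_index("cell_id")
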