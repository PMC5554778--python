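"""Bivalent-chromatin quantification: H3K4me3 / H3K27me3 ratios.

For each gene-associated region the statistic is
log2((K4 + eps)/(K27 + eps)).  Regions are first restricted to
H3K4me3-bound sites (K4 score above a configurable floor).  Early-wave
lineage genes are expected to show a higher ratio (more active-mark
dominated) than late-wave genes, which carry relatively more of the
repressive mark.

Early and late regions are distinct sites, so the default between-label
test is the unpaired rank-sum; a signed-rank variant is provided for
explicitly paired region tables (paired in label order, truncated to the
shorter group, which is only meaningful when the caller supplies matched
regions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import NormalizedMatrix

__all__ = ["BivalencyResult", "compute_bivalency", "mark_bound_expression"]


@dataclass
class BivalencyResult:
    ratios: pd.DataFrame           # per-region log2 ratios with labels
    group_medians: dict[str, float]
    test: str
    statistic: float
    p_value: float
    direction: str                 # early_greater | late_greater | none


def compute_bivalency(coverage: pd.DataFrame,
                      gene_labels: Mapping[str, str],
                      epsilon: float = 1.0,
                      k4_min: float = 0.0,
                      test: str = "rank_sum") -> BivalencyResult:
    """Per-region log2((K4+eps)/(K27+eps)) and the early-vs-late test.

    ``coverage`` needs columns region_id, gene_id, k4_score, k27_score;
    ``gene_labels`` maps genes to 'early' or 'late' (unlabeled genes are
    grouped as 'other' and excluded from the test).  Each tested label
    needs >= 3 regions.
    """
    if not epsilon > 0:
        raise ValueError("epsilon must be > 0")
    if (coverage[["k4_score", "k27_score"]] < 0).to_numpy().any():
        raise ValueError("mark scores must be non-negative")

    df = coverage[coverage["k4_score"] > k4_min].copy()
    df["label"] = [gene_labels.get(g, "other") for g in df["gene_id"]]
    df["log2_ratio"] = np.log2((df["k4_score"] + epsilon) / (df["k27_score"] + epsilon))

    early = df.loc[df["label"] == "early", "log2_ratio"].to_numpy()
    late = df.loc[df["label"] == "late", "log2_ratio"].to_numpy()
    for name, arr in (("early", early), ("late", late)):
        if len(arr) < 3:
            raise ValueError(f"label {name!r} has {len(arr)} region(s); need >= 3")

    if test == "rank_sum":
        stat, p = stats.mannwhitneyu(early, late, alternative="two-sided")
    elif test == "signed_rank":
        k = min(len(early), len(late))
        if k < len(early) or k < len(late):
            warnings.warn("signed_rank pairs regions in label order and truncates "
                          "to the shorter group; supply matched regions for a "
                          "meaningful pairing", stacklevel=2)
        diff = early[:k] - late[:k]
        if np.allclose(diff, 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(early[:k], late[:k])
    else:
        raise ValueError(f"unknown test {test!r}")

    med = {lab: float(np.median(df.loc[df["label"] == lab, "log2_ratio"]))
           for lab in df["label"].unique()}
    if med["early"] > med["late"]:
        direction = "early_greater"
    elif med["late"] > med["early"]:
        direction = "late_greater"
    else:
        direction = "none"
    return BivalencyResult(ratios=df.set_index("region_id"),
                           group_medians=med, test=test,
                           statistic=float(stat), p_value=float(p),
                           direction=direction)


def mark_bound_expression(norm: NormalizedMatrix | pd.DataFrame,
                          groups: pd.Series,
                          bound_genes: Sequence[str],
                          group_a: str | None = None,
                          group_b: str | None = None) -> dict:
    """Compare mean expression of a mark-bound gene set between two groups.

    Computes each cell's mean normalized expression over the bound genes
    and applies the two-sided rank-sum test between the groups.  Returns
    a dict with per-cell scores, group medians, statistic, p and
    direction.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    present = [g for g in bound_genes if g in values.columns]
    if not present:
        raise ValueError("no bound genes present in the matrix")
    if len(present) == 1:
        warnings.warn("only one bound gene present; comparison proceeds on it",
                      stacklevel=2)
    groups = groups.astype(str)
    labels = pd.unique(groups)
    if group_a is None or group_b is None:
        if len(labels) != 2:
            raise ValueError("need exactly two groups (or pass group_a/group_b)")
        group_a, group_b = labels[0], labels[1]

    score = values.loc[groups.index, present].mean(axis=1)
    a = score[(groups == group_a).to_numpy()].to_numpy()
    b = score[(groups == group_b).to_numpy()].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_a > med_b:
        direction = "a_greater"
    elif med_b > med_a:
        direction = "b_greater"
    else:
        direction = "none"
    return {"scores": score, "group_a": group_a, "group_b": group_b,
            "median_a": med_a, "median_b": med_b,
            "statistic": float(stat), "p_value": float(p),
            "direction": direction, "n_genes_used": len(present)}
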