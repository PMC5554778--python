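"""Transcriptional noise as pairwise cell–cell Spearman distance.

Within a homogeneous cell group, every unordered pair of cells is scored
by d = (1 − rho) / 2, where rho is Spearman's rank correlation across a
gene set (typically the group's top-500 highly variable genes, or a
named set such as the cell-cycle genes).  d lies in [0, 1]: identical
expression ranks give 0, perfectly reversed ranks give 1.  Noisier
populations are more dispersed in expression space, so their pairwise-d
distribution shifts upward.

Group comparisons offer the rank-sum test on the pooled pairwise
distances (as used in the study, ignoring the dependence between pairs
that share a cell) and a permutation test that re-assigns *cell* group
labels — respecting exchangeability — and recomputes the difference of
median d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import NormalizedMatrix

__all__ = ["NoiseResult", "NoiseComparison", "PhaseComposition",
           "pairwise_noise", "noise_on_gene_set", "compare_noise",
           "phase_composition"]

PHASES = ("G1", "S", "G2M")


@dataclass
class NoiseResult:
    group_id: str
    n_cells: int
    gene_set_label: str
    pairwise_d: np.ndarray
    cells: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    n_undefined_cells: int = 0

    @property
    def summary_median(self) -> float:
        return float(np.median(self.pairwise_d))

    @property
    def summary_mean(self) -> float:
        return float(np.mean(self.pairwise_d))


@dataclass
class NoiseComparison:
    group_a: str
    group_b: str
    test: str
    statistic: float
    p_value: float
    direction: str  # a_greater | b_greater | none


@dataclass
class PhaseComposition:
    group_id: str
    counts: dict[str, int]
    fractions: dict[str, float]


def _values(norm: NormalizedMatrix | pd.DataFrame) -> pd.DataFrame:
    return norm.values if isinstance(norm, NormalizedMatrix) else norm


def _d_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full cell × cell d matrix; returns (d, defined-cell mask)."""
    ranks = stats.rankdata(values, axis=1)
    ok = np.ptp(ranks, axis=1) > 0
    d = np.full((values.shape[0],) * 2, np.nan)
    if ok.sum() >= 1:
        rho = np.corrcoef(ranks[ok])
        rho = np.atleast_2d(rho)
        sub = (1.0 - rho) / 2.0
        d[np.ix_(ok, ok)] = np.clip(sub, 0.0, 1.0)
    return d, ok


def pairwise_noise(norm: NormalizedMatrix | pd.DataFrame,
                   cells: Sequence[str],
                   genes: Sequence[str],
                   group_id: str = "",
                   gene_set_label: str = "") -> NoiseResult:
    """d = (1 − Spearman rho)/2 for every unordered pair of cells.

    Cells with zero variance across the gene list have undefined rank
    correlations; their pairs are excluded with a warning.
    """
    values = _values(norm)
    cells = list(cells)
    genes = list(genes)
    if len(cells) < 2:
        raise ValueError("need >= 2 cells")
    if len(genes) < 3:
        raise ValueError("need >= 3 genes")
    missing = [g for g in genes if g not in values.columns]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:5]}")

    sub = values.loc[cells, genes].to_numpy(dtype=float)
    d, ok = _d_matrix(sub)
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(f"{n_bad} cell(s) with zero variance excluded from pairs",
                      stacklevel=2)
    kept = np.flatnonzero(ok)
    iu = np.triu_indices(len(kept), k=1)
    pair_d = d[np.ix_(kept, kept)][iu]
    return NoiseResult(group_id=group_id, n_cells=len(kept),
                       gene_set_label=gene_set_label or f"{len(genes)} genes",
                       pairwise_d=pair_d,
                       cells=[cells[i] for i in kept], genes=genes,
                       n_undefined_cells=n_bad)


def noise_on_gene_set(norm: NormalizedMatrix | pd.DataFrame,
                      cells: Sequence[str],
                      named_set: Sequence[str],
                      group_id: str = "",
                      gene_set_label: str = "named set") -> NoiseResult:
    """Same statistic restricted to a named gene set (no HVG selection).

    Genes absent from the matrix are dropped; an empty intersection is an
    error.
    """
    values = _values(norm)
    present = [g for g in named_set if g in values.columns]
    if not present:
        raise ValueError("named gene set has no genes in common with the matrix")
    return pairwise_noise(values, cells, present, group_id=group_id,
                          gene_set_label=gene_set_label)


def _direction(med_a: float, med_b: float) -> str:
    if med_a > med_b:
        return "a_greater"
    if med_b > med_a:
        return "b_greater"
    return "none"


def compare_noise(a: NoiseResult, b: NoiseResult,
                  method: str = "wilcoxon_rank_sum",
                  norm: NormalizedMatrix | pd.DataFrame | None = None,
                  n_permutations: int = 1000,
                  seed: int = 0) -> NoiseComparison:
    """Compare two groups' noise distributions.

    ``wilcoxon_rank_sum`` applies the two-sided rank-sum test to the two
    pairwise-d vectors (pairs sharing a cell are treated as independent,
    as in the study).  ``permutation`` requires ``norm``: it computes d
    over the pooled cells on the union of the two gene sets once, then
    re-assigns cell group labels ``n_permutations`` times and recomputes
    the difference of median within-group d.
    """
    if len(a.pairwise_d) == 0 or len(b.pairwise_d) == 0:
        raise ValueError("both results must be non-empty")
    med_a, med_b = a.summary_median, b.summary_median

    if method == "wilcoxon_rank_sum":
        if np.array_equal(np.sort(a.pairwise_d), np.sort(b.pairwise_d)):
            direction = "none"
        else:
            direction = _direction(med_a, med_b)
        stat, p = stats.mannwhitneyu(a.pairwise_d, b.pairwise_d,
                                     alternative="two-sided")
        return NoiseComparison(a.group_id, b.group_id, method,
                               float(stat), float(p), direction)

    if method == "permutation":
        if norm is None:
            raise ValueError("permutation method requires the normalized matrix")
        values = _values(norm)
        genes = sorted(set(a.genes) | set(b.genes))
        cells = list(a.cells) + list(b.cells)
        sub = values.loc[cells, genes].to_numpy(dtype=float)
        d, ok = _d_matrix(sub)
        if not ok.all():
            keep = np.flatnonzero(ok)
            d = d[np.ix_(keep, keep)]
            labels_a = np.array([i < len(a.cells) for i in keep])
        else:
            labels_a = np.arange(len(cells)) < len(a.cells)
        n = d.shape[0]
        iu = np.triu_indices(n, k=1)

        def stat_for(mask_a: np.ndarray) -> float:
            same_a = mask_a[iu[0]] & mask_a[iu[1]]
            same_b = ~mask_a[iu[0]] & ~mask_a[iu[1]]
            da, db = d[iu][same_a], d[iu][same_b]
            if len(da) == 0 or len(db) == 0:
                return np.nan
            return float(np.median(da) - np.median(db))

        obs = stat_for(labels_a)
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(labels_a)
            s = stat_for(perm)
            if not np.isnan(s) and abs(s) >= abs(obs) - 1e-12:
                exceed += 1
        p = (1 + exceed) / (1 + n_permutations)
        direction = "none" if obs == 0 else _direction(med_a, med_b)
        return NoiseComparison(a.group_id, b.group_id, method, obs, p, direction)

    raise ValueError(f"unknown method {method!r}")


def phase_composition(cells: pd.DataFrame, group: str | None = None,
                      group_col: str = "group",
                      phase_col: str = "phase") -> PhaseComposition:
    """Cell-cycle phase counts and fractions for one group."""
    sub = cells if group is None else cells[cells[group_col] == group]
    if len(sub) == 0:
        raise ValueError(f"group {group!r} has no cells")
    phases = sub[phase_col]
    missing = sub.index[phases.isna() | (phases.astype(str) == "")].tolist()
    if missing:
        raise ValueError(f"cells without phase labels: {missing[:5]}")
    counts = {p: int((phases == p).sum()) for p in PHASES}
    extra = set(phases.unique()) - set(PHASES)
    if extra:
        raise ValueError(f"unknown phase labels: {sorted(extra)}")
    total = sum(counts.values())
    fractions = {p: c / total for p, c in counts.items()}
    return PhaseComposition(group_id=group or "all", counts=counts,
                            fractions=fractions)
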