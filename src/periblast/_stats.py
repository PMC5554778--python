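"""Shared rank-statistics helpers (vectorized Spearman screens, BH FDR)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["spearman_vs_covariate", "bh_adjust"]


def _rho_vs_covariate(values: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Spearman rho of each column of ``values`` against ``covariate``
    (mid-ranks for ties).  Zero-variance columns give NaN."""
    rg = stats.rankdata(values, axis=0)
    rc = stats.rankdata(covariate)
    rg = rg - rg.mean(axis=0)
    rc = rc - rc.mean()
    num = rg.T @ rc
    den = np.sqrt((rg**2).sum(axis=0) * (rc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / den, np.nan)
    return np.clip(rho, -1.0, 1.0)


def spearman_vs_covariate(values: pd.DataFrame, covariate: pd.Series,
                          pvalue_method: str = "auto",
                          n_permutations: int = 10000,
                          seed: int = 0) -> pd.DataFrame:
    """Spearman correlation of every gene (column) against a per-cell covariate.

    p-values use the t approximation (``"t"``); ``"permutation"`` draws
    seeded Monte-Carlo permutations of the covariate, shared across
    genes; ``"auto"`` switches to permutation below 10 cells, where the
    t approximation is poor.
    """
    cov = covariate.loc[values.index].to_numpy(dtype=float)
    n = len(cov)
    if n < 3:
        raise ValueError("need >= 3 cells")
    if np.ptp(cov) == 0:
        raise ValueError("covariate is constant across cells")
    X = values.to_numpy(dtype=float)
    rho = _rho_vs_covariate(X, cov)

    method = pvalue_method
    if method == "auto":
        method = "permutation" if n < 10 else "t"
    if method == "t":
        with np.errstate(invalid="ignore", divide="ignore"):
            t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        exceed = np.zeros(X.shape[1])
        obs = np.abs(rho)
        for _ in range(n_permutations):
            null = _rho_vs_covariate(X, rng.permutation(cov))
            exceed += np.abs(null) >= obs - 1e-12
        p = (1.0 + exceed) / (1.0 + n_permutations)
    else:
        raise ValueError(f"unknown pvalue_method {pvalue_method!r}")
    p = np.where(np.isnan(rho), np.nan, p)

    return pd.DataFrame({"rho": rho, "p_value": p}, index=values.columns.copy())


def bh_adjust(p: pd.Series | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (NaN-preserving)."""
    arr = np.asarray(p, dtype=float)
    out = np.full_like(arr, np.nan)
    ok = ~np.isnan(arr)
    if ok.any():
        out[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    return out
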