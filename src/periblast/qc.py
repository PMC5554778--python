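"""Cell-level quality control.

A cell is removed when any of the following holds:

* its well multiplicity is triplet, multiple, or empty (doublets are kept
  by default — the study retained them and reported robustness — with an
  option to drop);
* it expresses fewer than ``min_genes`` genes (a gene counts as expressed
  at count >= 1; the rule is strict: exactly ``min_genes`` passes);
* more than ``max_mito_fraction`` of its counts map to mitochondrial
  genes (strict: exactly the threshold passes);
* it expresses all three trophoblast markers (Elf5, Wnt7b, Tex19.1) at
  more than one count each.

Mitochondrial fraction is computed on raw counts, before normalization.
"""

from __future__ import annotations

from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse

from .config import QcConfig

__all__ = ["QcConfig", "detect_genes", "flag_trophoblast", "run_qc"]

_BAD_MULTIPLICITY = {"triplet", "multiple", "empty"}

FAIL_LOW_GENES = "low_genes"
FAIL_HIGH_MITO = "high_mito"
FAIL_MULTIPLET = "multiplet_or_empty"
FAIL_TROPHOBLAST = "trophoblast"


def _dense(X) -> np.ndarray:
    if scipy.sparse.issparse(X):
        return np.asarray(X.todense())
    return np.asarray(X)


def detect_genes(counts_row: np.ndarray) -> int:
    """Number of genes expressed (count >= 1) in one cell."""
    row = np.asarray(counts_row)
    if (row < 0).any():
        raise ValueError("counts must be non-negative")
    return int((row >= 1).sum())


def flag_trophoblast(counts_row: np.ndarray, gene_ids: pd.Index,
                     marker_genes: Sequence[str]) -> bool:
    """True iff every marker gene has more than one count in this cell."""
    missing = [m for m in marker_genes if m not in gene_ids]
    if missing:
        raise KeyError(f"marker genes absent from annotation: {missing}")
    pos = [gene_ids.get_loc(m) for m in marker_genes]
    row = np.asarray(counts_row)
    return bool((row[pos] > 1).all())


def run_qc(adata: ad.AnnData, config: QcConfig | None = None,
           ) -> tuple[ad.AnnData, pd.DataFrame]:
    """Apply the cell filters; returns (filtered AnnData, verdict table).

    The verdict table reports every input cell (kept and removed alike)
    with columns: n_genes_detected, mito_fraction, multiplicity,
    trophoblast_flag, pass, fail_reasons (comma-joined).
    """
    config = config or QcConfig()
    X = _dense(adata.X)
    n_cells = X.shape[0]

    totals = X.sum(axis=1)
    n_detected = (X >= 1).sum(axis=1)
    if "is_mito" in adata.var.columns:
        mito_mask = adata.var["is_mito"].to_numpy().astype(bool)
    else:
        mito_mask = np.zeros(X.shape[1], dtype=bool)
    mito_counts = X[:, mito_mask].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    if "multiplicity" in adata.obs.columns:
        multiplicity = adata.obs["multiplicity"].astype(str).to_numpy()
    else:
        multiplicity = np.full(n_cells, "single")

    if config.marker_genes is not None:
        troph = np.array([
            flag_trophoblast(X[i], adata.var_names, config.marker_genes)
            for i in range(n_cells)], dtype=bool) if n_cells else np.zeros(0, bool)
    else:
        troph = np.zeros(n_cells, dtype=bool)

    reasons: list[str] = []
    passes = np.ones(n_cells, dtype=bool)
    for i in range(n_cells):
        r = []
        m = multiplicity[i]
        if m in _BAD_MULTIPLICITY or (config.drop_doublets and m == "doublet"):
            r.append(FAIL_MULTIPLET)
        if n_detected[i] < config.min_genes:
            r.append(FAIL_LOW_GENES)
        if mito_frac[i] > config.max_mito_fraction:
            r.append(FAIL_HIGH_MITO)
        if troph[i]:
            r.append(FAIL_TROPHOBLAST)
        passes[i] = not r
        reasons.append(",".join(r))

    verdicts = pd.DataFrame({
        "n_genes_detected": n_detected.astype(int),
        "mito_fraction": mito_frac,
        "multiplicity": multiplicity,
        "trophoblast_flag": troph,
        "pass": passes,
        "fail_reasons": reasons,
    }, index=adata.obs_names.copy()).rename_axis("cell_id")

    return adata[passes].copy(), verdicts
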