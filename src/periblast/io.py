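"""Reading and writing the on-disk fixture formats.

A dataset directory contains:

* ``matrix.mtx``   — Matrix Market integer counts, genes × cells
  (cellranger orientation);
* ``genes.tsv``    — gene annotation (gene_id, chromosome, is_mito, plus
  any planted-truth columns);
* ``cells.tsv``    — per-cell metadata (embryo, stage, group, lineage,
  phase, multiplicity, batch, ...);
* optionally ``truth_cells.tsv`` / ``truth_genes.tsv`` / ``truth.json``
  for simulated data, and ``chromatin.bed`` for mark coverage.

Mark coverage is stored as BED6+2: chrom, start, end, name (region id),
score (H3K4me3), strand, then H3K27me3 and gene id as extra columns.
Coordinates are 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .simulate import GroundTruth

__all__ = ["write_fixture", "read_fixture", "write_mark_coverage",
           "read_mark_coverage", "read_gene_set", "write_gene_set"]

_BED_COLS = ["chrom", "start", "end", "region_id", "k4_score", "strand",
             "k27_score", "gene_id"]


def write_fixture(adata: ad.AnnData, directory: str | Path,
                  truth: GroundTruth | None = None,
                  coverage: pd.DataFrame | None = None) -> list[Path]:
    """Write a dataset (and optional truth / chromatin tables) to ``directory``.

    Returns the list of files written.  Round-trips through
    :func:`read_fixture`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    X = adata.X
    if scipy.sparse.issparse(X):
        X = X.toarray()
    mtx = scipy.sparse.csr_matrix(np.asarray(X).T.astype(np.int64))
    path = directory / "matrix.mtx"
    scipy.io.mmwrite(str(path), mtx, field="integer")
    written.append(path)

    genes = adata.var.copy()
    genes.index.name = "gene_id"
    path = directory / "genes.tsv"
    genes.to_csv(path, sep="\t")
    written.append(path)

    cells = adata.obs.copy()
    cells.index.name = "cell_id"
    path = directory / "cells.tsv"
    cells.to_csv(path, sep="\t")
    written.append(path)

    if truth is not None:
        path = directory / "truth_cells.tsv"
        truth.cells.to_csv(path, sep="\t")
        written.append(path)
        path = directory / "truth_genes.tsv"
        truth.genes.to_csv(path, sep="\t")
        written.append(path)
        path = directory / "truth.json"
        path.write_text(json.dumps({
            "dispersion_by_group": truth.dispersion_by_group,
            "x_dosage_by_stage_sex": {
                f"{s}|{x}": v for (s, x), v in truth.x_dosage_by_stage_sex.items()},
        }, indent=1, sort_keys=True))
        written.append(path)

    if coverage is not None:
        path = directory / "chromatin.bed"
        write_mark_coverage(coverage, path)
        written.append(path)
    return written


def _read_tsv(path: Path, index_col: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={index_col: str})
    return df.set_index(index_col)


def read_fixture(directory: str | Path) -> tuple[ad.AnnData, GroundTruth | None]:
    """Load a dataset directory written by :func:`write_fixture`."""
    directory = Path(directory)
    mtx = scipy.io.mmread(str(directory / "matrix.mtx"))
    X = np.asarray(scipy.sparse.csr_matrix(mtx).T.todense()).astype(np.int64)
    genes = _read_tsv(directory / "genes.tsv", "gene_id")
    cells = _read_tsv(directory / "cells.tsv", "cell_id")
    if "is_mito" in genes.columns:
        genes["is_mito"] = genes["is_mito"].astype(bool)
    if X.shape == (0, 0) and (len(cells) or len(genes)):
        X = np.zeros((len(cells), len(genes)), dtype=np.int64)
    adata = ad.AnnData(X=X, obs=cells, var=genes)

    truth = None
    if (directory / "truth_cells.tsv").exists():
        tc = _read_tsv(directory / "truth_cells.tsv", "cell_id")
        for col in ("doublet_partners",):
            if col in tc.columns:
                tc[col] = tc[col].fillna("")
        tg = _read_tsv(directory / "truth_genes.tsv", "gene_id")
        meta = json.loads((directory / "truth.json").read_text())
        truth = GroundTruth(
            cells=tc, genes=tg,
            dispersion_by_group=meta["dispersion_by_group"],
            x_dosage_by_stage_sex={
                tuple(k.split("|", 1)): v
                for k, v in meta["x_dosage_by_stage_sex"].items()})
    return adata, truth


def write_mark_coverage(coverage: pd.DataFrame, path: str | Path) -> None:
    """Write a mark-coverage table as BED6+2 (see module docstring)."""
    df = coverage.copy()
    if "strand" not in df.columns:
        df["strand"] = "."
    df[_BED_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_mark_coverage(path: str | Path) -> pd.DataFrame:
    """Read a BED6+2 mark-coverage file into a coverage table."""
    df = pd.read_csv(path, sep="\t", header=None, names=_BED_COLS,
                     dtype={"chrom": str, "region_id": str, "gene_id": str})
    bad = df["start"] >= df["end"]
    if bad.any():
        raise ValueError(f"regions with start >= end: {df.loc[bad, 'region_id'].tolist()[:5]}")
    return df


def read_gene_set(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_set(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + ("\n" if genes else ""))
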