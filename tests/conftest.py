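"""Shared fixtures: tiny hand-built matrices and seeded simulations."""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from periblast import ContaminantSpec, SimulationConfig, simulate_dataset


def make_adata(X: np.ndarray, chromosomes: list[str] | None = None,
               obs: pd.DataFrame | None = None,
               gene_ids: list[str] | None = None) -> ad.AnnData:
    """Hand-rolled AnnData with minimal annotation."""
    n_cells, n_genes = X.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    chromosomes = chromosomes or ["chr1"] * n_genes
    var = pd.DataFrame({"chromosome": chromosomes,
                        "is_mito": [c in ("chrM", "MT") for c in chromosomes]},
                       index=pd.Index(gene_ids, name="gene_id"))
    if obs is None:
        obs = pd.DataFrame(index=pd.Index([f"c{i}" for i in range(n_cells)],
                                          name="cell_id"))
    return ad.AnnData(X=np.asarray(X, dtype=np.int64), obs=obs, var=var)


def two_group_config(phi_a: float, phi_b: float, n_cells: int,
                     n_genes: int = 1000, seed: int = 0,
                     mean_range: tuple[float, float] = (5.0, 100.0),
                     ) -> SimulationConfig:
    """Two groups sharing gene means, differing only in NB dispersion."""
    return SimulationConfig(
        n_genes=n_genes,
        n_cells_per_group={"A": n_cells, "B": n_cells},
        stage_labels=("A", "B"),
        nb_mean_range=mean_range,
        dispersion_by_group={"A": phi_a, "B": phi_b},
        n_x_genes=0, n_y_genes=0, n_mito_genes=0,
        x_dosage_by_stage_sex={},
        n_lineage_genes_per_side=0, n_planted_regulators=0,
        n_lineage_drivers=0, n_phase_genes_per_phase=0,
        phase_fractions_by_group={},
        contaminant_spec=ContaminantSpec(),
        seed=seed)


@pytest.fixture(scope="session")
def default_sim():
    """One full-structure simulated embryo series, reused read-only."""
    cfg = SimulationConfig(seed=11, contaminant_spec=ContaminantSpec(
        n_low_complexity=4, n_high_mito=4, n_trophoblast=4, n_doublets=6,
        n_empty=2))
    return simulate_dataset(cfg)
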