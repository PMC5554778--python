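"""Generator contracts: determinism, planted structure, fixture round-trip."""

import numpy as np
import pandas as pd
import pytest

from periblast import (ConfigError, ContaminantSpec, SimulationConfig,
                       read_fixture, simulate_chromatin, simulate_dataset,
                       write_fixture)
from conftest import two_group_config


def small_cfg(**kw) -> SimulationConfig:
    base = dict(n_genes=300, n_cells_per_group={"E3.5": 30, "E4.5:epi": 15},
                stage_labels=("E3.5", "E4.5"),
                dispersion_by_group={"E3.5": 0.5, "E4.5:epi": 0.3},
                n_x_genes=20, n_y_genes=5, n_mito_genes=5,
                n_lineage_genes_per_side=10, n_planted_regulators=2,
                n_lineage_drivers=2, n_phase_genes_per_phase=5, seed=3)
    base.update(kw)
    return SimulationConfig(**base)


def test_same_config_same_seed_is_bit_identical():
    a1, t1 = simulate_dataset(small_cfg())
    a2, t2 = simulate_dataset(small_cfg())
    assert np.array_equal(a1.X, a2.X)
    pd.testing.assert_frame_equal(a1.obs, a2.obs)
    pd.testing.assert_frame_equal(t1.cells, t2.cells)
    a3, _ = simulate_dataset(small_cfg(seed=4))
    assert not np.array_equal(a1.X, a3.X)


def test_counts_are_nonnegative_integers():
    adata, _ = simulate_dataset(small_cfg())
    assert np.issubdtype(adata.X.dtype, np.integer)
    assert (adata.X >= 0).all()


def test_all_female_config_has_zero_y_counts():
    adata, truth = simulate_dataset(small_cfg(frac_female=1.0))
    assert (truth.cells["sex"] == "female").all()
    y = adata.var_names[(adata.var["chromosome"] == "chrY").to_numpy()]
    assert adata[:, y].X.sum() == 0


def test_every_cell_and_gene_has_one_truth_record():
    adata, truth = simulate_dataset(small_cfg(contaminant_spec=ContaminantSpec(
        n_low_complexity=1, n_doublets=2, n_empty=1)))
    assert truth.cells.index.equals(adata.obs_names)
    assert truth.genes.index.equals(adata.var_names)
    assert not truth.cells.index.duplicated().any()


def test_dispersion_knob_raises_cv2_at_equal_means():
    """Monte Carlo: with shared gene means, the noisier group's sample CV²
    exceeds the quieter group's for (nearly) every gene."""
    cfg = two_group_config(0.1, 2.0, n_cells=1000, n_genes=30, seed=5)
    adata, _ = simulate_dataset(cfg)
    grp = adata.obs["group"].to_numpy()
    X = adata.X.astype(float)

    def cv2(block):
        m = block.mean(axis=0)
        return block.var(axis=0, ddof=1) / m**2

    frac = (cv2(X[grp == "B"]) > cv2(X[grp == "A"])).mean()
    assert frac > 0.95


def test_female_x_dosage_recovered_from_mean_expression():
    cfg = SimulationConfig(
        n_genes=500, n_cells_per_group={"S": 200}, stage_labels=("S",),
        dispersion_by_group={"S": 0.3}, n_x_genes=50, n_y_genes=5,
        n_mito_genes=0, x_dosage_by_stage_sex={("S", "female"): 2.0},
        n_lineage_genes_per_side=0, n_planted_regulators=0,
        n_lineage_drivers=0, n_phase_genes_per_phase=0,
        phase_fractions_by_group={},
        embryo_sexes=("female", "male"), n_embryos_per_group=10, seed=2)
    adata, truth = simulate_dataset(cfg)
    x = (adata.var["chromosome"] == "chrX").to_numpy()
    fem = (truth.cells["sex"] == "female").to_numpy()
    ratio = adata.X[fem][:, x].mean() / adata.X[~fem][:, x].mean()
    assert ratio == pytest.approx(2.0, rel=0.10)


def test_positive_regulator_tracks_x_activity():
    cfg = small_cfg(n_planted_regulators=2, regulator_effect=2.0,
                    n_cells_per_group={"E3.5": 200},
                    dispersion_by_group={"E3.5": 0.3})
    adata, truth = simulate_dataset(cfg)
    from scipy import stats
    regs = truth.genes[truth.genes["gene_class"] == "regulator"]
    for g, sign in regs["regulator_sign"].items():
        col = adata[:, g].X.ravel()
        rho = stats.spearmanr(col, truth.cells["x_activity"]).statistic
        assert np.sign(rho) == sign and abs(rho) > 0.2


def test_contaminants_are_planted_as_specified(default_sim):
    adata, truth = default_sim
    counts = truth.cells["contaminant"].value_counts()
    assert counts["low_complexity"] == 4
    assert counts["high_mito"] == 4
    assert counts["trophoblast_like"] == 4
    assert counts["doublet"] == 6
    assert counts["empty_well"] == 2
    assert (adata.obs["multiplicity"] == "doublet").sum() == 6
    # doublet partners recorded and of the same group
    for cid, row in truth.cells[truth.cells["contaminant"] == "doublet"].iterrows():
        a, b = row["doublet_partners"].split("+")
        assert truth.cells.loc[a, "group"] == truth.cells.loc[b, "group"]
        np.testing.assert_array_equal(
            adata[cid].X.ravel(), adata[a].X.ravel() + adata[b].X.ravel())


@pytest.mark.parametrize("bad, msg", [
    (dict(dispersion_by_group={"E3.5": -1.0, "E4.5:epi": 0.3}), "dispersion"),
    (dict(phase_fractions_by_group={"E3.5": (0.5, 0.5, 0.5)}), "sum to 1"),
    (dict(frac_female=1.5), "frac_female"),
    (dict(x_dosage_by_stage_sex={("E3.5", "female"): 0.0}), "x_dosage"),
])
def test_invalid_config_names_offending_field(bad, msg):
    with pytest.raises(ConfigError, match=msg):
        simulate_dataset(small_cfg(**bad))


# ---- chromatin ------------------------------------------------------------

def test_chromatin_unit_ratio_centers_log_ratio_at_zero():
    cov = simulate_chromatin({"s": [f"g{i}" for i in range(200)]}, {"s": 1.0},
                             seed=0, sigma=0.5)
    logr = np.log2(cov["k4_score"] / cov["k27_score"])
    assert abs(logr.mean()) < 0.25


def test_chromatin_label_ratios_order_medians():
    cov = simulate_chromatin(
        {"early": [f"e{i}" for i in range(200)],
         "late": [f"l{i}" for i in range(200)]},
        {"early": 4.0, "late": 0.5}, seed=1, sigma=0.5)
    med = cov.groupby("label").apply(
        lambda d: np.median(np.log2(d["k4_score"] / d["k27_score"])),
        include_groups=False)
    assert med["early"] > med["late"]


def test_chromatin_zero_noise_is_exact():
    cov = simulate_chromatin({"s": ["g"]}, {"s": 3.0}, seed=0, sigma=0.0)
    assert cov["k4_score"].iloc[0] / cov["k27_score"].iloc[0] == pytest.approx(3.0)


def test_chromatin_overlapping_sets_error():
    with pytest.raises(ConfigError, match="overlap"):
        simulate_chromatin({"a": ["g1"], "b": ["g1"]}, {"a": 1.0, "b": 2.0})


# ---- fixture round-trip ---------------------------------------------------

def test_fixture_round_trip(tmp_path, default_sim):
    adata, truth = default_sim
    write_fixture(adata, tmp_path / "fx", truth=truth)
    back, truth2 = read_fixture(tmp_path / "fx")
    assert np.array_equal(np.asarray(back.X), np.asarray(adata.X))
    assert back.obs_names.equals(adata.obs_names)
    assert back.var_names.equals(adata.var_names)
    assert (back.obs["multiplicity"] == adata.obs["multiplicity"]).all()
    assert truth2 is not None
    assert (truth2.cells["contaminant"] == truth.cells["contaminant"]).all()
    assert truth2.dispersion_by_group == truth.dispersion_by_group
    # exactly the planted number of doublet rows in the cell table
    cells_tsv = pd.read_csv(tmp_path / "fx" / "cells.tsv", sep="\t")
    assert (cells_tsv["multiplicity"] == "doublet").sum() == 6


def test_fixture_round_trip_zero_cells(tmp_path):
    cfg = small_cfg(n_cells_per_group={"E3.5": 0, "E4.5:epi": 0})
    adata, truth = simulate_dataset(cfg)
    write_fixture(adata, tmp_path / "fx0", truth=truth)
    back, _ = read_fixture(tmp_path / "fx0")
    assert back.n_obs == 0
    assert back.n_vars == adata.n_vars
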