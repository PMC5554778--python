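"""Lineage gene-set derivation, symmetry-breaking ratios, driver screen,
and quadrant mapping."""

import numpy as np
import pandas as pd
import pytest

from periblast import (LineageGeneSets, SimulationConfig, assign_quadrant,
                       derive_lineage_sets, driver_screen, flag_intermediate,
                       lineage_ratio, simulate_dataset)
from periblast.normalize import normalize_cpm


def _committed_cfg(seed=0, n_per_side=20, n_cells=26):
    return SimulationConfig(
        n_genes=600, n_cells_per_group={"C:epi": n_cells, "C:pre": n_cells},
        stage_labels=("C",), dispersion_by_group={"C:epi": 0.4, "C:pre": 0.4},
        n_x_genes=0, n_y_genes=0, n_mito_genes=0, x_dosage_by_stage_sex={},
        n_lineage_genes_per_side=n_per_side, n_planted_regulators=0,
        n_lineage_drivers=0, n_phase_genes_per_phase=0,
        phase_fractions_by_group={}, seed=seed)


def _derive(adata, truth):
    norm = normalize_cpm(adata, policy="autosomes_only")
    labels = adata.obs["lineage"].astype(str)
    return derive_lineage_sets(norm.values, labels)


def test_planted_programs_recovered_into_correct_sets():
    adata, truth = simulate_dataset(_committed_cfg(seed=1))
    sets = _derive(adata, truth)
    epi_true = set(truth.genes.index[truth.genes["gene_class"] == "lineage_epi"])
    pre_true = set(truth.genes.index[truth.genes["gene_class"] == "lineage_pre"])
    assert len(set(sets.epiblast_genes) & epi_true) >= 0.9 * len(epi_true)
    assert len(set(sets.pre_genes) & pre_true) >= 0.9 * len(pre_true)
    # no planted gene lands in the wrong set
    assert not set(sets.epiblast_genes) & pre_true
    assert not set(sets.pre_genes) & epi_true


def test_swapping_labels_swaps_sets_exactly():
    adata, truth = simulate_dataset(_committed_cfg(seed=2))
    norm = normalize_cpm(adata, policy="autosomes_only")
    labels = adata.obs["lineage"].astype(str)
    fwd = derive_lineage_sets(norm.values, labels)
    swapped = labels.map({"epi": "pre", "pre": "epi"})
    rev = derive_lineage_sets(norm.values, swapped)
    assert fwd.epiblast_genes == rev.pre_genes
    assert fwd.pre_genes == rev.epiblast_genes


def test_null_populations_give_empty_sets():
    adata, _ = simulate_dataset(_committed_cfg(seed=3, n_per_side=0))
    norm = normalize_cpm(adata, policy="autosomes_only")
    # same generative process for both labels: no true DE
    sets = derive_lineage_sets(norm.values, adata.obs["lineage"].astype(str))
    assert len(sets.epiblast_genes) + len(sets.pre_genes) == 0


def test_selection_requires_both_significance_and_fold_change():
    rng = np.random.default_rng(4)
    base = rng.gamma(5.0, 4.0, size=(20, 5))
    vals = pd.DataFrame(base, index=[f"c{i}" for i in range(20)],
                        columns=[f"g{i}" for i in range(5)])
    # significant but small fold change (lfc ~ 1.3 < 2)
    vals.iloc[:10, 0] = 25.0
    vals.iloc[10:, 0] = 9.0
    labels = pd.Series(["epi"] * 10 + ["pre"] * 10, index=vals.index)
    sets = derive_lineage_sets(vals, labels)
    assert sets.table.loc["g0", "adjusted_p"] <= 0.05
    assert "g0" not in sets.epiblast_genes


def test_wave_labels_follow_uncommitted_detection():
    sets_genes = ["e1", "e2"]
    unc = pd.DataFrame({"e1": [1, 1, 1, 0], "e2": [0, 0, 0, 1]},
                       index=[f"u{i}" for i in range(4)])
    from periblast.lineage import label_waves
    waves = label_waves(sets_genes, unc, early_detect_frac=0.25)
    assert waves == {"e1": "early", "e2": "late"}


def test_lineage_ratio_arithmetic_and_undefined_flag():
    counts = pd.DataFrame(
        {"e1": [1, 0, 0], "e2": [3, 0, 0], "p1": [2, 1, 0], "p2": [1, 1, 0]},
        index=["both", "pre_only", "neither"])
    sets = LineageGeneSets(["e1", "e2"], ["p1", "p2"])
    tbl = lineage_ratio(counts, sets)
    assert tbl.loc["both", "ratio"] == pytest.approx(0.5)
    assert tbl.loc["pre_only", "ratio"] == 0.0
    assert bool(tbl.loc["neither", "undefined"]) is True
    inter = flag_intermediate(tbl)
    assert bool(inter["both"]) is True and bool(inter["pre_only"]) is False
    with pytest.raises(ValueError, match="empty"):
        lineage_ratio(counts, LineageGeneSets([], []))


def test_ratio_uses_detection_not_magnitude():
    counts = pd.DataFrame({"e1": [1], "p1": [400]}, index=["c"])
    sets = LineageGeneSets(["e1"], ["p1"])
    assert lineage_ratio(counts, sets).loc["c", "ratio"] == pytest.approx(0.5)


def test_committed_ratios_are_bimodal_versus_uncommitted():
    cfg = SimulationConfig(
        n_genes=600, n_cells_per_group={"U": 40, "C:epi": 20, "C:pre": 20},
        stage_labels=("U", "C"),
        dispersion_by_group={"U": 0.5, "C:epi": 0.4, "C:pre": 0.4},
        n_x_genes=0, n_y_genes=0, n_mito_genes=0, x_dosage_by_stage_sex={},
        n_lineage_genes_per_side=50, n_planted_regulators=0,
        n_lineage_drivers=0, n_phase_genes_per_phase=0,
        phase_fractions_by_group={}, seed=5)
    adata, truth = simulate_dataset(cfg)
    g = truth.genes
    sets = LineageGeneSets(g.index[g["gene_class"] == "lineage_epi"].tolist(),
                           g.index[g["gene_class"] == "lineage_pre"].tolist())
    counts = pd.DataFrame(np.asarray(adata.X), index=adata.obs_names,
                          columns=adata.var_names)
    tbl = lineage_ratio(counts, sets)
    unc = adata.obs_names[(adata.obs["group"] == "U").to_numpy()]
    com = adata.obs_names[(adata.obs["group"] != "U").to_numpy()]
    dev = (tbl["ratio"] - 0.5).abs()
    assert dev[com].median() > dev[unc].median()


def test_driver_gene_equal_to_ratio_has_rho_one():
    rng = np.random.default_rng(6)
    n = 20
    ratios = pd.DataFrame({"ratio": rng.uniform(0.1, 0.9, n),
                           "undefined": False},
                          index=[f"c{i}" for i in range(n)])
    vals = pd.DataFrame(rng.gamma(2, 10, size=(n, 5)),
                        index=ratios.index,
                        columns=[f"g{i}" for i in range(5)])
    vals["mirror"] = ratios["ratio"] * 100
    scr = driver_screen(vals, ratios, min_mean=0.0)
    assert scr.loc["mirror", "rho"] == pytest.approx(1.0)
    assert scr.index[0] == "mirror"


def test_driver_screen_preconditions():
    ratios = pd.DataFrame({"ratio": [0.5] * 12, "undefined": False},
                          index=[f"c{i}" for i in range(12)])
    vals = pd.DataFrame(np.random.default_rng(0).gamma(2, 10, (12, 4)),
                        index=ratios.index)
    with pytest.raises(ValueError, match="identical"):
        driver_screen(vals, ratios, min_mean=0.0)
    with pytest.raises(ValueError, match=">= 10 cells"):
        driver_screen(vals.iloc[:5], ratios.iloc[:5], min_mean=0.0)


def test_permuted_ratios_yield_fdr_controlled_positives():
    rng = np.random.default_rng(7)
    n = 60
    vals = pd.DataFrame(rng.gamma(2, 10, size=(n, 300)),
                        index=[f"c{i}" for i in range(n)],
                        columns=[f"g{i}" for i in range(300)])
    ratios = pd.DataFrame({"ratio": rng.permutation(np.linspace(0, 1, n)),
                           "undefined": False}, index=vals.index)
    scr = driver_screen(vals, ratios, min_mean=0.0)
    assert (scr["adjusted_p"] < 0.05).mean() <= 0.05


def test_quadrant_assignment_recovers_source_profile():
    rng = np.random.default_rng(8)
    n_genes = 200
    ref = pd.DataFrame(rng.gamma(2, 10, size=(n_genes, 4)),
                       index=[f"g{i}" for i in range(n_genes)],
                       columns=["AP", "AD", "PD", "PP"])
    cells, labels = [], []
    for q in ref.columns:
        for _ in range(25):
            cells.append(ref[q].to_numpy() * np.exp(rng.normal(0, 0.2, n_genes)))
            labels.append(q)
    vals = pd.DataFrame(cells, columns=ref.index,
                        index=[f"c{i}" for i in range(100)])
    res = assign_quadrant(vals, ref)
    assert (res["quadrant"].to_numpy() == np.array(labels)).mean() >= 0.95


def test_quadrant_ties_and_degenerate_cells_flagged():
    ref = pd.DataFrame({"A": np.arange(60.0), "B": np.arange(60.0)},
                       index=[f"g{i}" for i in range(60)])
    vals = pd.DataFrame([np.arange(60.0), np.ones(60)],
                        columns=ref.index, index=["ok", "flat"])
    res = assign_quadrant(vals, ref)
    assert bool(res.loc["ok", "tie"]) is True          # identical references
    assert bool(res.loc["flat", "undefined"]) is True  # constant cell
    with pytest.raises(ValueError, match="shared"):
        assign_quadrant(vals.iloc[:, :10], ref.iloc[:10])
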