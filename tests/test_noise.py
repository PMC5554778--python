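"""Pairwise-distance noise statistic: oracle equivalence, invariances,
group comparisons, and phase composition."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from periblast import (compare_noise, noise_on_gene_set, pairwise_noise,
                       phase_composition, simulate_dataset)
from periblast.normalize import normalize_cpm, gene_variability, select_hvg
from conftest import two_group_config


def _df(X):
    return pd.DataFrame(np.asarray(X, dtype=float),
                        index=[f"c{i}" for i in range(X.shape[0])],
                        columns=[f"g{i}" for i in range(X.shape[1])])


def test_identical_cells_have_zero_distance():
    vals = _df(np.array([[1, 5, 3, 2], [1, 5, 3, 2]]))
    res = pairwise_noise(vals, vals.index, vals.columns)
    assert res.pairwise_d == pytest.approx([0.0])


def test_rank_reversed_cells_have_unit_distance():
    vals = _df(np.array([[1, 2, 3, 4, 5], [5, 4, 3, 2, 1]]))
    res = pairwise_noise(vals, vals.index, vals.columns)
    assert res.pairwise_d == pytest.approx([1.0])


def test_vectorized_equals_naive_spearman_loop():
    """Oracle: per-pair scipy.stats.spearmanr over 20 cells × 200 genes."""
    rng = np.random.default_rng(0)
    vals = _df(rng.gamma(2.0, 10.0, size=(20, 200)))
    res = pairwise_noise(vals, vals.index, vals.columns)
    X = vals.to_numpy()
    expected = []
    for i in range(20):
        for j in range(i + 1, 20):
            rho = stats.spearmanr(X[i], X[j]).statistic
            expected.append((1 - rho) / 2)
    np.testing.assert_allclose(res.pairwise_d, expected, atol=1e-12)
    assert len(res.pairwise_d) == 20 * 19 // 2
    assert ((res.pairwise_d >= 0) & (res.pairwise_d <= 1)).all()


def test_statistic_invariant_to_per_cell_scaling():
    rng = np.random.default_rng(1)
    vals = _df(rng.gamma(2.0, 10.0, size=(10, 50)))
    scaled = vals.mul(rng.uniform(0.5, 5.0, size=10), axis=0)
    r1 = pairwise_noise(vals, vals.index, vals.columns)
    r2 = pairwise_noise(scaled, vals.index, vals.columns)
    np.testing.assert_allclose(r1.pairwise_d, r2.pairwise_d, atol=1e-12)


def test_zero_variance_cell_is_excluded_with_warning():
    X = np.array([[1, 2, 3, 4], [4, 4, 4, 4], [2, 1, 4, 3]], dtype=float)
    vals = _df(X)
    with pytest.warns(UserWarning, match="zero variance"):
        res = pairwise_noise(vals, vals.index, vals.columns)
    assert res.n_undefined_cells == 1
    assert res.n_cells == 2
    assert len(res.pairwise_d) == 1


def test_preconditions():
    vals = _df(np.ones((5, 5)) + np.arange(5)[:, None])
    with pytest.raises(ValueError, match=">= 2 cells"):
        pairwise_noise(vals, ["c0"], vals.columns)
    with pytest.raises(ValueError, match=">= 3 genes"):
        pairwise_noise(vals, vals.index, ["g0", "g1"])
    with pytest.raises(KeyError):
        pairwise_noise(vals, vals.index, ["g0", "g1", "nope"])


def test_gene_set_restriction_matches_pairwise_on_same_set():
    rng = np.random.default_rng(2)
    vals = _df(rng.gamma(2.0, 10.0, size=(8, 30)))
    subset = ["g3", "g7", "g11", "g20"]
    r1 = pairwise_noise(vals, vals.index, subset)
    r2 = noise_on_gene_set(vals, vals.index, subset)
    np.testing.assert_allclose(r1.pairwise_d, r2.pairwise_d)
    with pytest.raises(ValueError, match="no genes in common"):
        noise_on_gene_set(vals, vals.index, ["zz"])


def test_gene_set_noise_isolates_planted_cell_cycle_effect():
    """When only the cell-cycle-labeled genes differ in dispersion between
    groups, the gene-set statistic separates the groups more than the
    statistic on the complementary genes."""
    rng = np.random.default_rng(3)
    n, g_cc, g_other = 40, 60, 240
    means_cc = np.exp(rng.uniform(np.log(10), np.log(80), g_cc))
    means_ot = np.exp(rng.uniform(np.log(10), np.log(80), g_other))

    def sample(phi_cc, phi_ot):
        lam_cc = rng.gamma(1 / phi_cc, means_cc * phi_cc, size=(n, g_cc))
        lam_ot = rng.gamma(1 / phi_ot, means_ot * phi_ot, size=(n, g_other))
        return np.hstack([rng.poisson(lam_cc), rng.poisson(lam_ot)])

    A = sample(0.1, 0.3)
    B = sample(2.0, 0.3)
    vals = _df(np.vstack([A, B]))
    cc_genes = [f"g{i}" for i in range(g_cc)]
    other_genes = [f"g{i}" for i in range(g_cc, g_cc + g_other)]
    cells_a, cells_b = vals.index[:n], vals.index[n:]

    diff_cc = (noise_on_gene_set(vals, cells_b, cc_genes).summary_median
               - noise_on_gene_set(vals, cells_a, cc_genes).summary_median)
    diff_ot = (noise_on_gene_set(vals, cells_b, other_genes).summary_median
               - noise_on_gene_set(vals, cells_a, other_genes).summary_median)
    assert diff_cc > 0.05
    assert diff_cc > diff_ot + 0.02


def test_median_d_nondecreasing_along_dispersion_ladder():
    for seed in range(3):
        medians = []
        for phi in (0.1, 0.5, 1.5):
            cfg = two_group_config(phi, phi, n_cells=50, n_genes=400, seed=seed)
            adata, _ = simulate_dataset(cfg)
            cells = adata.obs_names[(adata.obs["group"] == "A").to_numpy()]
            norm = normalize_cpm(adata)
            hvg = gene_variability(norm, cells=cells, min_mean=10.0, window=101,
                                   filter_means=pd.Series(
                                       np.asarray(adata[cells].X).mean(axis=0),
                                       index=adata.var_names))
            res = pairwise_noise(norm, cells, select_hvg(hvg, 200))
            medians.append(res.summary_median)
        assert medians == sorted(medians)


def test_compare_noise_rank_sum_identical_gives_no_direction():
    a = pairwise_noise(_df(np.random.default_rng(1).gamma(2, 10, (6, 20))),
                       [f"c{i}" for i in range(6)], [f"g{i}" for i in range(20)],
                       group_id="A")
    cmp = compare_noise(a, a)
    assert cmp.direction == "none"
    assert cmp.p_value == pytest.approx(1.0)
    with pytest.raises(ValueError, match="unknown method"):
        compare_noise(a, a, method="bogus")


def test_permutation_test_needs_matrix_and_detects_planted_difference():
    rng = np.random.default_rng(4)
    means = np.exp(rng.uniform(np.log(5), np.log(100), size=200))
    quiet = rng.poisson(rng.gamma(1 / 0.05, means * 0.05, size=(25, 200)))
    noisy = rng.poisson(rng.gamma(1 / 2.0, means * 2.0, size=(25, 200)))
    vals = _df(np.vstack([quiet, noisy]))
    ca, cb = vals.index[:25], vals.index[25:]
    a = pairwise_noise(vals, ca, vals.columns, group_id="quiet")
    b = pairwise_noise(vals, cb, vals.columns, group_id="noisy")
    with pytest.raises(ValueError, match="requires the normalized matrix"):
        compare_noise(a, b, method="permutation")
    cmp = compare_noise(a, b, method="permutation", norm=vals,
                        n_permutations=200, seed=0)
    assert cmp.p_value < 0.05
    assert cmp.direction == "b_greater"


def test_phase_composition_counts_and_errors():
    cells = pd.DataFrame({"group": ["x"] * 10, "phase": ["G1"] * 10},
                         index=[f"c{i}" for i in range(10)])
    pc = phase_composition(cells, group="x")
    assert pc.fractions == {"G1": 1.0, "S": 0.0, "G2M": 0.0}
    with pytest.raises(ValueError, match="no cells"):
        phase_composition(cells, group="y")
    cells.loc["c3", "phase"] = None
    with pytest.raises(ValueError, match="without phase"):
        phase_composition(cells, group="x")


def test_phase_fractions_recovered_from_multinomial_sampling():
    rng = np.random.default_rng(5)
    fracs = (0.05, 0.35, 0.60)
    labels = rng.choice(["G1", "S", "G2M"], p=fracs, size=100)
    cells = pd.DataFrame({"group": "ps", "phase": labels},
                         index=[f"c{i}" for i in range(100)])
    pc = phase_composition(cells, group="ps")
    for target, phase in zip(fracs, ("G1", "S", "G2M")):
        assert abs(pc.fractions[phase] - target) <= 0.1
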