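"""Synthetic peri-implantation embryo dataset generator.

Emulates the statistical structure the downstream analyses assume:
negative-binomial counts with group-specific dispersion, a lognormal
library-size factor per cell, sex-structured X/Y-linked dosage across
stages, salt-and-pepper lineage co-expression at the uncommitted stage
versus mutually exclusive programs after commitment, cell-cycle phase
signatures, regulator genes coupled to each cell's X activity, and
contaminant cells (low-complexity, high-mitochondrial, trophoblast-like,
doublets, empty wells).  Every planted effect is recorded in a
:class:`GroundTruth` object.

Counts are parameterized as mean/dispersion with variance
``mu + phi * mu**2`` and sampled as a gamma–Poisson mixture, so the
dispersion knob moves CV² independently of the mean (CV² = 1/mu + phi).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .config import (PHASES, TROPHOBLAST_MARKERS, ConfigError, SimulationConfig,
                     parse_group_label)

__all__ = ["GroundTruth", "simulate_dataset", "simulate_chromatin"]


@dataclass
class GroundTruth:
    """Per-cell / per-gene planted truth for a simulated dataset."""

    cells: pd.DataFrame     # sex, group, stage, lineage, phase, contaminant, doublet_partners, x_activity
    genes: pd.DataFrame     # gene_class, regulator_sign, wave, phase, base_mean
    dispersion_by_group: dict[str, float]
    x_dosage_by_stage_sex: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def clean_cells(self) -> pd.Index:
        """Cells carrying no planted QC violation (doublets count as clean-ish
        but are flagged by multiplicity, so they are excluded here)."""
        ok = self.cells["contaminant"] == "none"
        return self.cells.index[ok]


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial via gamma–Poisson; phi == 0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if phi <= 1e-12:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam)


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    if size == 0:
        return np.zeros(0)
    if hi == lo:
        return np.full(size, float(lo))
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def _build_gene_table(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Gene annotation plus planted per-gene truth columns."""
    n_epi, n_pre = cfg.lineage_sizes
    n_phase = cfg.n_phase_genes_per_phase * len(PHASES)
    n_special = (n_epi + n_pre + cfg.n_planted_regulators + cfg.n_lineage_drivers
                 + n_phase + len(TROPHOBLAST_MARKERS) + cfg.n_x_genes
                 + cfg.n_y_genes + cfg.n_mito_genes)
    if n_special > cfg.n_genes:
        raise ConfigError(
            f"n_genes={cfg.n_genes} too small for {n_special} special genes")
    n_plain = cfg.n_genes - n_special

    rows: list[dict] = []

    def add(n: int, gene_class: str, chrom: str | None, means: np.ndarray,
            **extra) -> None:
        for i in range(n):
            rows.append(dict(gene_class=gene_class, chromosome=chrom,
                             base_mean=float(means[i]), regulator_sign=0,
                             wave="", phase="", **extra))

    add(n_plain, "autosomal", None, _loguniform(rng, *cfg.nb_mean_range, n_plain))
    add(n_epi, "lineage_epi", None, _loguniform(rng, *cfg.lineage_off_mean_range, n_epi))
    add(n_pre, "lineage_pre", None, _loguniform(rng, *cfg.lineage_off_mean_range, n_pre))

    reg_means = _loguniform(rng, *cfg.regulator_mean_range, cfg.n_planted_regulators)
    reg_signs = np.where(np.arange(cfg.n_planted_regulators) % 2 == 0, 1, -1)
    for i in range(cfg.n_planted_regulators):
        rows.append(dict(gene_class="regulator", chromosome=None,
                         base_mean=float(reg_means[i]),
                         regulator_sign=int(reg_signs[i]), wave="", phase=""))

    drv_means = _loguniform(rng, *cfg.regulator_mean_range, cfg.n_lineage_drivers)
    drv_signs = np.where(np.arange(cfg.n_lineage_drivers) % 2 == 0, 1, -1)
    for i in range(cfg.n_lineage_drivers):
        rows.append(dict(gene_class="lineage_driver", chromosome=None,
                         base_mean=float(drv_means[i]),
                         regulator_sign=int(drv_signs[i]), wave="", phase=""))

    for phase in PHASES:
        means = _loguniform(rng, 1.0, 5.0, cfg.n_phase_genes_per_phase)
        for i in range(cfg.n_phase_genes_per_phase):
            rows.append(dict(gene_class="phase_signature", chromosome=None,
                             base_mean=float(means[i]), regulator_sign=0,
                             wave="", phase=phase))

    for name in TROPHOBLAST_MARKERS:
        rows.append(dict(gene_class="trophoblast_marker", chromosome=None,
                         base_mean=0.05, regulator_sign=0, wave="", phase="",
                         gene_name=name))

    add(cfg.n_x_genes, "x_linked", "chrX", _loguniform(rng, *cfg.nb_mean_range, cfg.n_x_genes))
    add(cfg.n_y_genes, "y_linked", "chrY", _loguniform(rng, 0.5, 3.0, cfg.n_y_genes))
    add(cfg.n_mito_genes, "mito", "chrM", _loguniform(rng, 20.0, 80.0, cfg.n_mito_genes))

    genes = pd.DataFrame(rows)

    # Early/late wave membership of lineage genes.
    lineage_mask = genes["gene_class"].isin(["lineage_epi", "lineage_pre"])
    for cls in ("lineage_epi", "lineage_pre"):
        idx = genes.index[genes["gene_class"] == cls]
        n_early = int(round(cfg.frac_early_wave * len(idx)))
        genes.loc[idx[:n_early], "wave"] = "early"
        genes.loc[idx[n_early:], "wave"] = "late"
    assert (genes.loc[lineage_mask, "wave"] != "").all()

    # Stable ids; named markers keep their marker names.
    ids = [f"G{i:05d}" for i in range(len(genes))]
    if "gene_name" in genes.columns:
        named = genes["gene_name"].notna()
        for i in genes.index[named]:
            ids[i] = genes.loc[i, "gene_name"]
        genes = genes.drop(columns="gene_name")
    genes.index = pd.Index(ids, name="gene_id")

    # Autosome assignment, round-robin over chr1..chr19.
    auto = genes["chromosome"].isna()
    autosomes = [f"chr{i}" for i in range(1, 20)]
    genes.loc[auto, "chromosome"] = [autosomes[i % 19] for i in range(int(auto.sum()))]
    genes["is_mito"] = genes["chromosome"] == "chrM"
    return genes


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _cell_means(cfg: SimulationConfig, rng: np.random.Generator,
                genes: pd.DataFrame, group: str, sex: str, phase: str,
                ) -> tuple[np.ndarray, float, float, float]:
    """Expected counts for one cell.

    Returns (means, library_factor, x_activity, lineage_bias_logit).
    """
    stage, lineage = parse_group_label(group)
    base = genes["base_mean"].to_numpy().copy()
    lib = float(np.exp(rng.normal(0.0, cfg.library_sigma)))
    jitter = float(np.exp(rng.normal(0.0, cfg.x_activity_sigma)))
    x_act = cfg.x_dosage(stage, sex) * jitter
    uncommitted = lineage is None and stage == cfg.stage_labels[0]
    bias = float(rng.normal(0.0, cfg.lineage_bias_sigma)) if uncommitted else 0.0

    cls = genes["gene_class"].to_numpy()
    base[cls == "x_linked"] *= x_act
    base[cls == "y_linked"] *= 0.0 if sex == "female" else 1.0

    # Lineage programs.
    on = cfg.lineage_strength
    p0 = min(max(cfg.lineage_coexpression_prob, 1e-9), 1 - 1e-9)
    logit_p0 = np.log(p0 / (1 - p0))
    for side, own in (("lineage_epi", "epi"), ("lineage_pre", "pre")):
        mask = cls == side
        if not mask.any():
            continue
        if lineage in ("epi", "pre"):
            base[mask] *= on if lineage == own else 1.0
        elif uncommitted:
            # Salt-and-pepper co-expression, odds tilted by the cell's bias
            # (positive bias favors the epiblast program).
            p = _sigmoid(logit_p0 + (bias if own == "epi" else -bias))
            early = mask & (genes["wave"].to_numpy() == "early")
            late = mask & (genes["wave"].to_numpy() == "late")
            coex = rng.random(int(early.sum())) < p
            base[early] *= np.where(coex, on, 1.0)
            base[late] *= cfg.late_wave_silencing
        # other groups (post-segregation epiblast, streak): baseline leak.

    # Cell-cycle signature.
    phase_genes = (cls == "phase_signature") & (genes["phase"].to_numpy() == phase)
    base[phase_genes] *= cfg.phase_boost

    # Regulators couple to the cell's X-activity jitter; drivers to its
    # lineage-bias logit.
    reg = cls == "regulator"
    if reg.any():
        signs = genes["regulator_sign"].to_numpy()[reg]
        base[reg] *= jitter ** (signs * cfg.regulator_effect)
    drv = cls == "lineage_driver"
    if drv.any():
        signs = genes["regulator_sign"].to_numpy()[drv]
        base[drv] *= np.exp(signs * cfg.driver_effect * bias)

    return base * lib, lib, x_act, bias


def simulate_dataset(config: SimulationConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate a count matrix with cell metadata and recorded ground truth.

    Returns an :class:`anndata.AnnData` (cells × genes, integer counts in
    ``X``, annotation in ``var``, metadata in ``obs``) and the matching
    :class:`GroundTruth`.  Identical ``config`` (including ``seed``)
    reproduces the matrix bit-exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _build_gene_table(config, rng)

    counts: list[np.ndarray] = []
    obs_rows: list[dict] = []
    truth_rows: list[dict] = []
    embryo_counter = 0
    sex_cycle = 0

    group_cell_idx: dict[str, list[int]] = {g: [] for g in config.n_cells_per_group}

    # Plan embryos and their sexes up front.  The emulated study design has
    # multiple embryos of both sexes at every stage, so when sexes are drawn
    # (not overridden) and a stage with >= 2 embryos comes out single-sex,
    # one embryo is flipped.
    group_embryos: dict[str, list[str]] = {}
    embryo_sex: dict[str, str] = {}
    stage_embryos: dict[str, list[str]] = {}
    for group, n_cells in config.n_cells_per_group.items():
        stage, _ = parse_group_label(group)
        n_embryos = min(config.n_embryos_per_group, max(n_cells, 1))
        ids = [f"emb{embryo_counter + i:03d}" for i in range(n_embryos)]
        embryo_counter += n_embryos
        group_embryos[group] = ids
        stage_embryos.setdefault(stage, []).extend(ids)
        for eid in ids:
            if config.embryo_sexes is not None:
                embryo_sex[eid] = config.embryo_sexes[sex_cycle % len(config.embryo_sexes)]
                sex_cycle += 1
            else:
                embryo_sex[eid] = "female" if rng.random() < config.frac_female else "male"
    if config.embryo_sexes is None and 0.0 < config.frac_female < 1.0:
        for stage, ids in stage_embryos.items():
            if len(ids) >= 2 and len({embryo_sex[e] for e in ids}) == 1:
                flip = ids[-1]
                embryo_sex[flip] = "male" if embryo_sex[flip] == "female" else "female"

    for group, n_cells in config.n_cells_per_group.items():
        stage, lineage = parse_group_label(group)
        embryo_ids = group_embryos[group]
        n_embryos = len(embryo_ids)
        fracs = np.asarray(config.phase_fractions(group), dtype=float)

        for i in range(n_cells):
            eid = embryo_ids[i % n_embryos]
            sex = embryo_sex[eid]
            phase = PHASES[int(rng.choice(len(PHASES), p=fracs))]
            means, lib, x_act, bias = _cell_means(config, rng, genes, group, sex, phase)
            row = _nb_sample(rng, means, config.dispersion_by_group[group])
            cell_id = f"cell{len(counts):05d}"
            group_cell_idx[group].append(len(counts))
            counts.append(row)
            obs_rows.append(dict(cell_id=cell_id, embryo=eid, stage=stage,
                                 group=group, lineage=lineage or "none",
                                 phase=phase, multiplicity="single",
                                 batch=f"batch{int(eid[3:]) // 2:02d}"))
            truth_rows.append(dict(cell_id=cell_id, sex=sex, group=group,
                                   stage=stage, lineage=lineage or "none",
                                   phase=phase, contaminant="none",
                                   doublet_partners="", x_activity=x_act,
                                   lineage_bias=bias, library_factor=lib))

    # ---- contaminants -------------------------------------------------
    spec = config.contaminant_spec
    groups = list(config.n_cells_per_group)
    cls_arr = genes["gene_class"].to_numpy()

    def _fresh_cell(group: str) -> tuple[np.ndarray, dict, dict]:
        stage, lineage = parse_group_label(group)
        sex = "female" if rng.random() < config.frac_female else "male"
        phase = PHASES[int(rng.choice(len(PHASES),
                                      p=np.asarray(config.phase_fractions(group))))]
        means, lib, x_act, bias = _cell_means(config, rng, genes, group, sex, phase)
        meta = dict(embryo="embX", stage=stage, group=group,
                    lineage=lineage or "none", phase=phase,
                    multiplicity="single", batch="batchX")
        truth = dict(sex=sex, group=group, stage=stage, lineage=lineage or "none",
                     phase=phase, doublet_partners="", x_activity=x_act,
                     lineage_bias=bias, library_factor=lib)
        return means, meta, truth

    def _append(row: np.ndarray, meta: dict, truth: dict, contaminant: str) -> None:
        cell_id = f"cell{len(counts):05d}"
        counts.append(row)
        obs_rows.append(dict(cell_id=cell_id, **meta))
        truth_rows.append(dict(cell_id=cell_id, contaminant=contaminant, **truth))

    for k in range(spec.n_low_complexity):
        group = groups[k % len(groups)]
        means, meta, truth = _fresh_cell(group)
        drop = rng.random(len(means)) < 0.8
        means = np.where(drop, 0.0, means)
        row = _nb_sample(rng, means, config.dispersion_by_group[group])
        _append(row, meta, truth, "low_complexity")

    for k in range(spec.n_high_mito):
        group = groups[k % len(groups)]
        means, meta, truth = _fresh_cell(group)
        means[cls_arr == "mito"] *= 8.0
        row = _nb_sample(rng, means, config.dispersion_by_group[group])
        # The violation is guaranteed by construction: double the
        # mitochondrial load until it exceeds 10% of the library.
        mito = cls_arr == "mito"
        if mito.any():
            row[mito] = np.maximum(row[mito], 1)
            while row[mito].sum() <= 0.10 * row.sum():
                row[mito] *= 2
        _append(row, meta, truth, "high_mito")

    for k in range(spec.n_trophoblast):
        group = groups[k % len(groups)]
        means, meta, truth = _fresh_cell(group)
        means[cls_arr == "trophoblast_marker"] = 30.0
        row = _nb_sample(rng, means, config.dispersion_by_group[group])
        # Marker-positive by construction (> 1 count in each marker).
        row[cls_arr == "trophoblast_marker"] = np.maximum(
            row[cls_arr == "trophoblast_marker"], 2)
        _append(row, meta, truth, "trophoblast_like")

    n_single = len(counts)
    for k in range(spec.n_doublets):
        group = groups[k % len(groups)]
        pool = group_cell_idx[group]
        if len(pool) < 2:
            raise ConfigError(f"contaminant_spec.n_doublets: group {group!r} has "
                              "fewer than 2 cells to pair")
        i, j = rng.choice(len(pool), size=2, replace=False)
        a, b = pool[int(i)], pool[int(j)]
        row = counts[a] + counts[b]
        meta = dict(obs_rows[a])
        del meta["cell_id"]
        meta["multiplicity"] = "doublet"
        truth = dict(truth_rows[a])
        del truth["cell_id"], truth["contaminant"]
        truth["doublet_partners"] = f"{obs_rows[a]['cell_id']}+{obs_rows[b]['cell_id']}"
        _append(row, meta, truth, "doublet")

    for k in range(spec.n_empty):
        group = groups[k % len(groups)]
        means, meta, truth = _fresh_cell(group)
        row = _nb_sample(rng, means * 1e-3, 0.0)
        meta["multiplicity"] = "empty"
        _append(row, meta, truth, "empty_well")

    X = (np.vstack(counts) if counts
         else np.zeros((0, len(genes)), dtype=np.int64)).astype(np.int64)
    obs = pd.DataFrame(obs_rows).set_index("cell_id") if obs_rows else \
        pd.DataFrame(columns=["embryo", "stage", "group", "lineage", "phase",
                              "multiplicity", "batch"]).rename_axis("cell_id")
    truth_cells = pd.DataFrame(truth_rows).set_index("cell_id") if truth_rows else \
        pd.DataFrame(columns=["sex", "group", "stage", "lineage", "phase",
                              "contaminant", "doublet_partners", "x_activity",
                              "library_factor"]).rename_axis("cell_id")

    adata = ad.AnnData(X=X, obs=obs, var=genes.copy())
    truth = GroundTruth(cells=truth_cells, genes=genes.copy(),
                        dispersion_by_group=dict(config.dispersion_by_group),
                        x_dosage_by_stage_sex=dict(config.x_dosage_by_stage_sex))
    return adata, truth


def simulate_chromatin(gene_sets: Mapping[str, Sequence[str]],
                       k4_k27_ratio_by_label: Mapping[str, float],
                       seed: int = 0,
                       sigma: float = 0.5,
                       base_level: float = 100.0) -> pd.DataFrame:
    """Simulate H3K4me3/H3K27me3 coverage, one region per gene.

    The expected log2(K4/K27) of a label's regions equals
    log2 of its configured ratio; each mark carries independent lognormal
    noise of log-sd ``sigma``.  Returns a mark-coverage table with columns
    region_id, chrom, start, end, gene_id, label, k4_score, k27_score.
    """
    seen: set[str] = set()
    for label, gs in gene_sets.items():
        overlap = seen & set(gs)
        if overlap:
            raise ConfigError(f"gene_sets overlap at {sorted(overlap)[:5]}")
        seen |= set(gs)
        if label not in k4_k27_ratio_by_label:
            raise ConfigError(f"k4_k27_ratio_by_label missing label {label!r}")
        if not k4_k27_ratio_by_label[label] > 0:
            raise ConfigError(f"k4_k27_ratio_by_label[{label!r}] must be > 0")

    rng = np.random.default_rng(seed)
    rows = []
    pos = 0
    for label, gs in gene_sets.items():
        ratio = float(k4_k27_ratio_by_label[label])
        for g in gs:
            noise4 = np.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
            noise27 = np.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
            k4 = base_level * np.sqrt(ratio) * noise4
            k27 = base_level / np.sqrt(ratio) * noise27
            rows.append(dict(region_id=f"region_{g}", chrom="chr1",
                             start=pos * 2000, end=pos * 2000 + 2000,
                             gene_id=g, label=label,
                             k4_score=float(k4), k27_score=float(k27)))
            pos += 1
    return pd.DataFrame(rows)
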