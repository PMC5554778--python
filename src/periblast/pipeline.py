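"""End-to-end orchestration: simulate/load → QC → normalize → HVG → noise
→ X chromosome → lineage → bivalency, with every table written to disk, a
JSON summary of headline statistics, and a MANIFEST of emitted files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from . import __version__
from .bivalency import compute_bivalency
from .config import RunConfig, parse_group_label
from .io import read_fixture, read_mark_coverage, write_fixture
from .lineage import derive_lineage_sets, driver_screen, flag_intermediate, lineage_ratio
from .noise import compare_noise, pairwise_noise, phase_composition
from .normalize import gene_variability, normalize_cpm, select_hvg
from .qc import run_qc
from .simulate import simulate_chromatin, simulate_dataset
from .xchrom import assign_sex, dosage_ratios, x_correlation_screen, x_proportion

log = logging.getLogger("periblast")


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the summary dict (also written
    as ``summary.json``).  Identical config + seed reproduces the summary
    bit-exactly."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    emitted: list[Path] = []
    incomplete: list[str] = []
    summary: dict = {
        "tool": "periblast",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
    }

    def save_df(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t")
        emitted.append(path)

    # ---- input -------------------------------------------------------
    stage = "input"
    try:
        if config.simulate is not None:
            sim_cfg = config.simulate
            adata, truth = simulate_dataset(sim_cfg)
            emitted += write_fixture(adata, out / "simulated", truth=truth)
            log.info("simulated %d cells x %d genes", adata.n_obs, adata.n_vars)
        else:
            adata, truth = read_fixture(config.input_dir)
            log.info("loaded %d cells x %d genes from %s",
                     adata.n_obs, adata.n_vars, config.input_dir)
        summary["n_cells_input"] = int(adata.n_obs)
        summary["n_genes"] = int(adata.n_vars)
    except Exception as e:  # pragma: no cover - fatal
        raise StageError(stage, e) from e

    # ---- qc ------------------------------------------------------------
    stage = "qc"
    try:
        filtered, verdicts = run_qc(adata, config.qc)
        save_df(verdicts, "qc_verdicts.tsv")
        summary["n_cells_pass_qc"] = int(verdicts["pass"].sum())
        summary["qc_fail_reason_counts"] = {
            r: int(verdicts["fail_reasons"].str.contains(r).sum())
            for r in ("low_genes", "high_mito", "multiplet_or_empty", "trophoblast")}
        log.info("QC kept %d / %d cells", filtered.n_obs, adata.n_obs)
    except Exception as e:
        raise StageError(stage, e) from e

    counts_df = pd.DataFrame(np.asarray(filtered.X), index=filtered.obs_names,
                             columns=filtered.var_names)

    # ---- normalize + HVG ----------------------------------------------
    stage = "normalize"
    try:
        norm = normalize_cpm(filtered, policy="autosomes_only")
        hvg_all = gene_variability(norm, min_mean=config.hvg.min_mean_counts,
                                   window=config.hvg.window,
                                   filter_means=counts_df.mean(axis=0))
        save_df(hvg_all, "hvg_table.tsv")
    except Exception as e:
        raise StageError(stage, e) from e

    groups = filtered.obs["group"].astype(str)
    group_cells = {g: filtered.obs_names[(groups == g).to_numpy()].tolist()
                   for g in pd.unique(groups)}

    # ---- noise ---------------------------------------------------------
    stage = "noise"
    noise_results = {}
    try:
        rows = []
        for g, cells in group_cells.items():
            if len(cells) < 5:
                log.warning("group %s has %d cells; skipped for noise", g, len(cells))
                continue
            hvg_g = gene_variability(norm, cells=cells,
                                     min_mean=config.hvg.min_mean_counts,
                                     window=config.hvg.window,
                                     filter_means=counts_df.loc[cells].mean(axis=0))
            top = select_hvg(hvg_g, config.noise.n_hvg)
            res = pairwise_noise(norm, cells, top, group_id=g,
                                 gene_set_label=f"top{config.noise.n_hvg}_hvg")
            noise_results[g] = res
            rows.append(dict(group=g, n_cells=res.n_cells,
                             n_pairs=len(res.pairwise_d),
                             median_d=res.summary_median,
                             mean_d=res.summary_mean))
        noise_table = pd.DataFrame(rows).set_index("group")
        save_df(noise_table, "noise_by_group.tsv")
        summary["noise_median_d_by_group"] = {
            g: round(float(m), 6) for g, m in noise_table["median_d"].items()}

        comp_rows = []
        for a, b in config.noise.comparisons:
            if a not in noise_results or b not in noise_results:
                log.warning("comparison %s vs %s skipped (missing group)", a, b)
                continue
            wil = compare_noise(noise_results[a], noise_results[b],
                                method="wilcoxon_rank_sum")
            perm = compare_noise(noise_results[a], noise_results[b],
                                 method="permutation", norm=norm,
                                 n_permutations=config.noise.permutations,
                                 seed=config.seed)
            for c in (wil, perm):
                comp_rows.append(dict(group_a=a, group_b=b, test=c.test,
                                      statistic=c.statistic, p_value=c.p_value,
                                      direction=c.direction))
        if comp_rows:
            save_df(pd.DataFrame(comp_rows), "noise_comparisons.tsv")
            summary["noise_comparisons"] = [
                {k: (round(v, 6) if isinstance(v, float) else v) for k, v in r.items()}
                for r in comp_rows]

        phase_rows = []
        for g, cells in group_cells.items():
            try:
                pc = phase_composition(filtered.obs.loc[cells], group=None,
                                       phase_col="phase")
            except ValueError:
                continue
            phase_rows.append(dict(group=g, **pc.counts,
                                   **{f"frac_{k}": round(v, 4)
                                      for k, v in pc.fractions.items()}))
        if phase_rows:
            save_df(pd.DataFrame(phase_rows).set_index("group"),
                    "phase_composition.tsv")
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- X chromosome --------------------------------------------------
    stage = "xchrom"
    try:
        sexes = assign_sex(filtered, threshold=config.xchrom.y_threshold)
        save_df(sexes, "sex_assignment.tsv")
        ratios = dosage_ratios(filtered, sexes,
                               chromosomes=list(config.xchrom.ratio_chromosomes))
        save_df(ratios.set_index(["stage", "chromosome"]), "dosage_ratios.tsv")
        xr = ratios[(ratios["chromosome"] == "chrX") & ~ratios["undefined"]]
        summary["x_dosage_ratio_by_stage"] = {
            r["stage"]: round(float(r["ratio"]), 4) for _, r in xr.iterrows()}
        xprop = x_proportion(filtered)
        save_df(xprop, "x_proportion.tsv")

        if config.xchrom.screen_stage is not None:
            screen = x_correlation_screen(
                filtered, config.xchrom.screen_stage, sexes=sexes,
                lineage=[l for l in pd.unique(filtered.obs["lineage"].astype(str))
                         if l != "pre"],
                female_only=config.xchrom.female_only,
                min_mean=config.xchrom.min_mean, seed=config.seed)
            save_df(screen, "x_correlation_screen.tsv")
            top = screen.head(10)
            summary["x_screen_top_genes"] = {
                g: round(float(r), 4) for g, r in top["rho"].items()}
    except Exception as e:
        log.error("stage %s failed: %s", stage, e)
        incomplete.append(stage)

    # ---- lineage -------------------------------------------------------
    stage = "lineage"
    sets = None
    try:
        lc = config.lineage
        if lc.committed_group_epi and lc.committed_group_pre:
            committed = [c for g in (lc.committed_group_epi, lc.committed_group_pre)
                         for c in group_cells.get(g, [])]
            labels = filtered.obs.loc[committed, "lineage"].astype(str)
            uncommitted = group_cells.get(lc.uncommitted_group or "", [])
            sets = derive_lineage_sets(
                norm.values.loc[committed], labels,
                epiblast_label="epi", pre_label="pre",
                lfc_threshold=lc.lfc, fdr=lc.fdr,
                uncommitted_counts=counts_df.loc[uncommitted] if uncommitted else None,
                early_detect_frac=lc.early_detect_frac)
            save_df(sets.table, "lineage_de_table.tsv")
            set_df = pd.DataFrame(
                [(g, "epi", sets.wave.get(g, "")) for g in sets.epiblast_genes]
                + [(g, "pre", sets.wave.get(g, "")) for g in sets.pre_genes],
                columns=["gene_id", "set", "wave"]).set_index("gene_id")
            save_df(set_df, "lineage_gene_sets.tsv")
            summary["n_epiblast_genes"] = len(sets.epiblast_genes)
            summary["n_pre_genes"] = len(sets.pre_genes)

            ratio_cells = uncommitted + committed
            ratios_tbl = lineage_ratio(counts_df.loc[ratio_cells], sets)
            ratios_tbl["intermediate"] = flag_intermediate(
                ratios_tbl, band=lc.intermediate_band)
            save_df(ratios_tbl, "lineage_ratios.tsv")
            if uncommitted:
                med_unc = float(np.nanmedian(
                    np.abs(ratios_tbl.loc[uncommitted, "ratio"] - 0.5)))
                med_com = float(np.nanmedian(
                    np.abs(ratios_tbl.loc[committed, "ratio"] - 0.5)))
                summary["lineage_ratio_abs_dev_median"] = {
                    "uncommitted": round(med_unc, 4), "committed": round(med_com, 4)}
                drivers = driver_screen(norm.values, ratios_tbl.loc[uncommitted],
                                        sets=sets, min_mean=1.0,
                                        raw_counts=counts_df, seed=config.seed)
                save_df(drivers, "driver_screen.tsv")
                summary["driver_screen_top_genes"] = {
                    g: round(float(r), 4) for g, r in drivers.head(10)["rho"].items()}
    except Exception as e:
        log.error("stage %s failed: %s", stage, e)
        incomplete.append(stage)

    # ---- bivalency -----------------------------------------------------
    stage = "bivalency"
    try:
        coverage = None
        wave_labels: dict[str, str] = {}
        if config.input_dir and (Path(config.input_dir) / "chromatin.bed").exists():
            coverage = read_mark_coverage(Path(config.input_dir) / "chromatin.bed")
            if sets is not None:
                wave_labels = sets.wave
        elif sets is not None and sets.wave:
            early = sorted(g for g, w in sets.wave.items() if w == "early")
            late = sorted(g for g, w in sets.wave.items() if w == "late")
            if len(early) >= 3 and len(late) >= 3:
                coverage = simulate_chromatin(
                    {"early": early, "late": late},
                    {"early": config.bivalency.sim_ratio_early,
                     "late": config.bivalency.sim_ratio_late},
                    seed=config.seed, sigma=config.bivalency.sim_sigma)
                wave_labels = sets.wave
        if coverage is not None and wave_labels:
            biv = compute_bivalency(coverage, wave_labels,
                                    epsilon=config.bivalency.epsilon,
                                    k4_min=config.bivalency.k4_min)
            save_df(biv.ratios, "bivalency_ratios.tsv")
            summary["bivalency"] = {
                "median_log2_ratio_early": round(biv.group_medians.get("early", np.nan), 4),
                "median_log2_ratio_late": round(biv.group_medians.get("late", np.nan), 4),
                "p_value": float(biv.p_value),
                "direction": biv.direction,
            }
    except Exception as e:
        log.error("stage %s failed: %s", stage, e)
        incomplete.append(stage)

    if config.make_plots:
        try:
            from .plots import plot_dosage_ratios, plot_noise_distributions
            p1 = out / "noise_distributions.png"
            plot_noise_distributions(list(noise_results.values()), p1)
            emitted.append(p1)
            p2 = out / "x_dosage_ratios.png"
            plot_dosage_ratios(ratios, p2)
            emitted.append(p2)
        except Exception as e:  # plots are diagnostics only
            log.warning("plotting failed: %s", e)

    # ---- summary + manifest -------------------------------------------
    summary["incomplete_stages"] = incomplete
    spath = out / "summary.json"
    spath.write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    emitted.append(spath)

    manifest = out / "MANIFEST"
    lines = [f"{_sha256(p)}  {p.relative_to(out)}" for p in sorted(set(emitted))]
    if incomplete:
        lines.append(f"# INCOMPLETE: {','.join(incomplete)}")
    manifest.write_text("\n".join(lines) + "\n")
    return summary
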