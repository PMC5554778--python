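"""Configuration objects for the simulator and the end-to-end pipeline.

Group labels follow the convention ``"<stage>"`` for an uncommitted
population (e.g. ``"E3.5"``) and ``"<stage>:<lineage>"`` for a committed
one (e.g. ``"E4.5:epi"``, ``"E4.5:pre"``, ``"E6.5:ps"``).  The stage part
keys the X-dosage trajectory; the lineage part selects the expression
program of the planted lineage genes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


def parse_group_label(label: str) -> tuple[str, str | None]:
    """Split ``"stage[:lineage]"`` into (stage, lineage-or-None)."""
    if ":" in label:
        stage, lineage = label.split(":", 1)
        return stage, lineage
    return label, None


@dataclass
class ContaminantSpec:
    """Counts of deliberately broken cells appended to the clean matrix."""

    n_low_complexity: int = 0
    n_high_mito: int = 0
    n_trophoblast: int = 0
    n_doublets: int = 0
    n_empty: int = 0

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int,)) or v < 0:
                raise ConfigError(f"contaminant_spec.{f.name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return (self.n_low_complexity + self.n_high_mito + self.n_trophoblast
                + self.n_doublets + self.n_empty)


def _default_groups() -> dict[str, int]:
    # Desk-scale embryo: group sizes follow the noise-analysis populations
    # (ICM, committed epiblast/PrE, post-implantation epiblast, streak).
    return {
        "E3.5": 99,
        "E4.5:epi": 26,
        "E4.5:pre": 26,
        "E5.5": 260,
        "E6.5:epi": 120,
        "E6.5:ps": 23,
    }


def _default_dispersions() -> dict[str, float]:
    # Free parameters: only the ordering (uncommitted noisy, streak quiet)
    # is meaningful, not the magnitudes.
    return {
        "E3.5": 0.8,
        "E4.5:epi": 0.4,
        "E4.5:pre": 0.4,
        "E5.5": 0.3,
        "E6.5:epi": 0.6,
        "E6.5:ps": 0.15,
    }


def _default_x_dosage() -> dict[tuple[str, str], float]:
    # Female X trajectory: partial reactivation at E3.5, both X active at
    # E4.5/E5.5, inactivation under way by E6.5.  Males stay at 1.
    return {
        ("E3.5", "female"): 1.3,
        ("E4.5", "female"): 2.0,
        ("E5.5", "female"): 1.8,
        ("E6.5", "female"): 1.0,
    }


def _default_phase_fractions() -> dict[str, tuple[float, float, float]]:
    # (G1, S, G2M).  The streak is G2M-enriched with a depleted G1.
    return {
        "E3.5": (0.5, 0.3, 0.2),
        "E4.5:epi": (0.5, 0.3, 0.2),
        "E4.5:pre": (0.5, 0.3, 0.2),
        "E5.5": (0.45, 0.3, 0.25),
        "E6.5:epi": (0.4, 0.3, 0.3),
        "E6.5:ps": (0.05, 0.35, 0.6),
    }


TROPHOBLAST_MARKERS = ("Elf5", "Wnt7b", "Tex19.1")

PHASES = ("G1", "S", "G2M")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic peri-implantation embryo dataset.

    Counts are drawn per gene × cell from a negative binomial with
    variance mu + phi * mu**2 (``dispersion_by_group`` supplies phi), on
    top of a per-cell lognormal library-size factor.  Structured effects
    (X dosage by stage and sex, Y-linked expression, lineage programs,
    cell-cycle phase signatures, regulators coupled to the cell's X
    activity) multiply the gene's baseline mean.
    """

    n_genes: int = 2000
    n_cells_per_group: dict[str, int] = field(default_factory=_default_groups)
    stage_labels: tuple[str, ...] = ("E3.5", "E4.5", "E5.5", "E6.5")
    nb_mean_range: tuple[float, float] = (0.2, 60.0)
    dispersion_by_group: dict[str, float] = field(default_factory=_default_dispersions)

    n_x_genes: int = 100
    n_y_genes: int = 10
    n_mito_genes: int = 15
    x_dosage_by_stage_sex: dict[tuple[str, str], float] = field(default_factory=_default_x_dosage)
    x_activity_sigma: float = 0.2

    n_lineage_genes_per_side: int | tuple[int, int] = 50
    lineage_strength: float = 8.0
    lineage_off_mean_range: tuple[float, float] = (0.2, 1.0)
    lineage_coexpression_prob: float = 0.3
    frac_early_wave: float = 0.5
    late_wave_silencing: float = 0.02

    n_planted_regulators: int = 6
    regulator_effect: float = 2.0
    regulator_mean_range: tuple[float, float] = (10.0, 40.0)

    # Uncommitted-stage symmetry breaking: each cell carries a latent
    # lineage-bias logit u ~ N(0, lineage_bias_sigma) shifting the
    # salt-and-pepper co-expression odds toward one program; driver genes
    # couple (with alternating sign) to u.
    lineage_bias_sigma: float = 0.5
    n_lineage_drivers: int = 4
    driver_effect: float = 2.0

    frac_female: float = 0.5
    embryo_sexes: tuple[str, ...] | None = None
    n_embryos_per_group: int = 4

    library_sigma: float = 0.3
    phase_fractions_by_group: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_phase_fractions)
    n_phase_genes_per_phase: int = 20
    phase_boost: float = 4.0

    contaminant_spec: ContaminantSpec = field(default_factory=ContaminantSpec)
    seed: int = 0

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        def _positive(name: str, value: float) -> None:
            if not value > 0:
                raise ConfigError(f"{name} must be > 0, got {value!r}")

        def _count(name: str, value: int) -> None:
            if not isinstance(value, int) or value < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {value!r}")

        _count("n_genes", self.n_genes)
        if not self.n_cells_per_group:
            raise ConfigError("n_cells_per_group must name at least one group")
        for g, n in self.n_cells_per_group.items():
            _count(f"n_cells_per_group[{g!r}]", n)
        lo, hi = self.nb_mean_range
        _positive("nb_mean_range[0]", lo)
        if hi < lo:
            raise ConfigError("nb_mean_range must be (low, high) with high >= low")
        for g in self.n_cells_per_group:
            phi = self.dispersion_by_group.get(g)
            if phi is None:
                raise ConfigError(f"dispersion_by_group missing group {g!r}")
            if phi < 0:
                raise ConfigError(f"dispersion_by_group[{g!r}] must be >= 0, got {phi!r}")
        if self.lineage_bias_sigma < 0:
            raise ConfigError("lineage_bias_sigma must be >= 0")
        for name in ("n_x_genes", "n_y_genes", "n_mito_genes",
                     "n_planted_regulators", "n_lineage_drivers",
                     "n_phase_genes_per_phase", "n_embryos_per_group"):
            _count(name, getattr(self, name))
        if self.n_embryos_per_group == 0:
            raise ConfigError("n_embryos_per_group must be >= 1")
        for key, mult in self.x_dosage_by_stage_sex.items():
            if not mult > 0:
                raise ConfigError(f"x_dosage_by_stage_sex[{key!r}] must be > 0, got {mult!r}")
        epi, pre = self.lineage_sizes
        _count("n_lineage_genes_per_side (epiblast side)", epi)
        _count("n_lineage_genes_per_side (PrE side)", pre)
        if not 0.0 <= self.lineage_coexpression_prob <= 1.0:
            raise ConfigError("lineage_coexpression_prob must lie in [0, 1]")
        if not 0.0 <= self.frac_early_wave <= 1.0:
            raise ConfigError("frac_early_wave must lie in [0, 1]")
        if not 0.0 <= self.frac_female <= 1.0:
            raise ConfigError("frac_female must lie in [0, 1]")
        if self.embryo_sexes is not None:
            bad = set(self.embryo_sexes) - {"female", "male"}
            if bad:
                raise ConfigError(f"embryo_sexes entries must be 'female'/'male', got {sorted(bad)}")
        for g, fracs in self.phase_fractions_by_group.items():
            if len(fracs) != len(PHASES) or any(f < 0 for f in fracs):
                raise ConfigError(f"phase_fractions_by_group[{g!r}] must be a {len(PHASES)}-part simplex")
            if abs(sum(fracs) - 1.0) > 1e-9:
                raise ConfigError(
                    f"phase_fractions_by_group[{g!r}] must sum to 1, got {sum(fracs)!r}")
        self.contaminant_spec.validate()

    @property
    def lineage_sizes(self) -> tuple[int, int]:
        """(epiblast-side, PrE-side) planted program sizes."""
        n = self.n_lineage_genes_per_side
        if isinstance(n, int):
            return n, n
        epi, pre = n
        return int(epi), int(pre)

    def group_stage(self, group: str) -> str:
        return parse_group_label(group)[0]

    def group_lineage(self, group: str) -> str | None:
        return parse_group_label(group)[1]

    def x_dosage(self, stage: str, sex: str) -> float:
        return self.x_dosage_by_stage_sex.get((stage, sex), 1.0)

    def phase_fractions(self, group: str) -> tuple[float, float, float]:
        return self.phase_fractions_by_group.get(group, (1 / 3, 1 / 3, 1 / 3))

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["x_dosage_by_stage_sex"] = {
            f"{stage}|{sex}": v for (stage, sex), v in self.x_dosage_by_stage_sex.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "x_dosage_by_stage_sex" in d:
            d["x_dosage_by_stage_sex"] = {
                tuple(k.split("|", 1)): float(v)
                for k, v in dict(d["x_dosage_by_stage_sex"]).items()}
        if "contaminant_spec" in d and isinstance(d["contaminant_spec"], Mapping):
            d["contaminant_spec"] = ContaminantSpec(**d["contaminant_spec"])
        for key in ("nb_mean_range", "lineage_off_mean_range", "regulator_mean_range",
                    "stage_labels"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "embryo_sexes" in d and isinstance(d["embryo_sexes"], list):
            d["embryo_sexes"] = tuple(d["embryo_sexes"])
        if "phase_fractions_by_group" in d:
            d["phase_fractions_by_group"] = {
                g: tuple(v) for g, v in dict(d["phase_fractions_by_group"]).items()}
        if "n_lineage_genes_per_side" in d and isinstance(d["n_lineage_genes_per_side"], list):
            d["n_lineage_genes_per_side"] = tuple(d["n_lineage_genes_per_side"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Pipeline configuration


@dataclass
class QcConfig:
    min_genes: int = 4000
    max_mito_fraction: float = 0.10
    marker_genes: tuple[str, str, str] | None = TROPHOBLAST_MARKERS
    drop_doublets: bool = False


@dataclass
class HvgConfig:
    window: int = 101
    min_mean_counts: float = 10.0
    n_top: int = 500


@dataclass
class NoiseConfig:
    n_hvg: int = 500
    permutations: int = 1000
    comparisons: tuple[tuple[str, str], ...] = ()


@dataclass
class XchromConfig:
    y_threshold: int = 10
    min_mean: float = 1.0
    screen_stage: str | None = None
    female_only: bool = True
    ratio_chromosomes: tuple[str, ...] = ("chrX", "chr1", "chr4", "chr6")


@dataclass
class LineageConfig:
    lfc: float = 2.0
    fdr: float = 0.05
    early_detect_frac: float = 0.25
    intermediate_band: tuple[float, float] = (0.3, 0.7)
    committed_group_epi: str | None = None
    committed_group_pre: str | None = None
    uncommitted_group: str | None = None


@dataclass
class BivalencyConfig:
    epsilon: float = 1.0
    k4_min: float = 0.0
    sim_ratio_early: float = 4.0
    sim_ratio_late: float = 0.5
    sim_sigma: float = 0.5


@dataclass
class RunConfig:
    """End-to-end pipeline configuration: exactly one of ``input_dir`` or
    ``simulate`` must be set."""

    input_dir: str | None = None
    simulate: SimulationConfig | None = None
    qc: QcConfig = field(default_factory=QcConfig)
    hvg: HvgConfig = field(default_factory=HvgConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    xchrom: XchromConfig = field(default_factory=XchromConfig)
    lineage: LineageConfig = field(default_factory=LineageConfig)
    bivalency: BivalencyConfig = field(default_factory=BivalencyConfig)
    out_dir: str = "periblast_out"
    seed: int = 0
    log_level: str = "INFO"
    make_plots: bool = False

    def validate(self) -> None:
        if (self.input_dir is None) == (self.simulate is None):
            raise ConfigError("exactly one of input_dir / simulate must be provided")
        if self.simulate is not None:
            self.simulate.validate()

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        if d.get("simulate") is not None:
            d["simulate"] = SimulationConfig.from_dict(d["simulate"])
        for key, sub in (("qc", QcConfig), ("hvg", HvgConfig), ("noise", NoiseConfig),
                         ("xchrom", XchromConfig), ("lineage", LineageConfig),
                         ("bivalency", BivalencyConfig)):
            if key in d and isinstance(d[key], Mapping):
                block = dict(d[key])
                for fname, fval in list(block.items()):
                    if isinstance(fval, list):
                        block[fname] = tuple(tuple(v) if isinstance(v, list) else v
                                             for v in fval) if fval and isinstance(fval[0], list) \
                            else tuple(fval)
                d[key] = sub(**block)
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def demo_config(seed: int = 0, out_dir: str = "periblast_out") -> RunConfig:
    """Self-contained demo: simulate an embryo series and analyze it.

    The QC gene threshold is scaled to the synthetic transcriptome size
    (2,000 genes, versus >20,000 in a real transcriptome where the
    4,000-detected-genes rule applies).
    """
    sim = SimulationConfig(seed=seed,
                           contaminant_spec=ContaminantSpec(
                               n_low_complexity=6, n_high_mito=6,
                               n_trophoblast=6, n_doublets=10, n_empty=4))
    cfg = RunConfig(
        simulate=sim,
        qc=QcConfig(min_genes=800),
        noise=NoiseConfig(comparisons=(("E3.5", "E4.5:epi"), ("E6.5:epi", "E6.5:ps"))),
        xchrom=XchromConfig(screen_stage="E5.5"),
        lineage=LineageConfig(committed_group_epi="E4.5:epi",
                              committed_group_pre="E4.5:pre",
                              uncommitted_group="E3.5"),
        out_dir=out_dir,
        seed=seed,
    )
    cfg.validate()
    return cfg
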