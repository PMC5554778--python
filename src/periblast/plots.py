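"""Diagnostic figures: pairwise-d distributions per group and the
female/male X dosage ratio per stage."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .noise import NoiseResult  # noqa: E402


def plot_noise_distributions(results: Sequence[NoiseResult], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(1.2 * max(len(results), 2) + 2, 4))
    data = [r.pairwise_d for r in results]
    labels = [f"{r.group_id}\n(n={r.n_cells})" for r in results]
    if data:
        ax.violinplot(data, showmedians=True)
        ax.set_xticks(range(1, len(labels) + 1), labels, fontsize=8)
    ax.set_ylabel("pairwise distance d = (1 − ρ)/2")
    ax.set_title("Transcriptional noise per group")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dosage_ratios(ratios: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for chrom, sub in ratios.groupby("chromosome"):
        sub = sub[~sub["undefined"]]
        ax.plot(sub["stage"], sub["ratio"], marker="o", label=chrom)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_ylabel("female / male median expression")
    ax.set_xlabel("stage")
    ax.legend(fontsize=8)
    ax.set_title("Sex dosage ratio per chromosome")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
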