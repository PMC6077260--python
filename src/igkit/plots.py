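"""Optional figure rendering for the pipeline reports.

All plots are derived from the TSV tables the pipeline writes anyway; the
core analysis never depends on this module, so runs with plotting disabled
have no graphics overhead.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def bar_chart(table: pd.DataFrame, path: Path, title: str, xlabel: str) -> None:
    if table.empty:
        return
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(table)), 3.5))
    ax.bar(table["label"].astype(str), table["frequency"], color="#4878d0")
    ax.set_title(title)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("frequency")
    plt.xticks(rotation=90, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pie_chart(table: pd.DataFrame, path: Path, title: str) -> None:
    if table.empty:
        return
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.pie(table["frequency"], labels=table["label"].astype(str), autopct="%1.1f%%")
    ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def kaks_boxplot(profiles: pd.DataFrame, path: Path) -> None:
    if profiles.empty:
        return
    fig, ax = plt.subplots(figsize=(4, 3.5))
    ratios = profiles["ka_ks_ratio"].dropna()
    ax.boxplot(
        [profiles["ka_per_codon"], profiles["ks_per_codon"], ratios],
        tick_labels=["Ka", "Ks", "Ka/Ks"],
    )
    ax.set_ylabel("mutations per codon")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def expansion_plot(expansion: pd.DataFrame, path: Path, k: int) -> None:
    if expansion.empty:
        return
    top = expansion.head(k)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(top["rank"] - 0.2, top["y_reads"], width=0.4, label="reads (y)", color="#4878d0")
    ax.bar(top["rank"] + 0.2, top["x_unique_aa"], width=0.4, label="unique AA (x)", color="#6acc64")
    ax.set_xlabel("clone rank")
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def venn_diagram(region_counts: dict[tuple[int, ...], int], n: int, path: Path) -> None:
    """Simple 2- or 3-set Venn rendering; callers emit a table for any n."""
    if n not in (2, 3):
        return
    fig, ax = plt.subplots(figsize=(4.5, 4))
    centers = {2: [(-0.5, 0), (0.5, 0)], 3: [(-0.5, 0.3), (0.5, 0.3), (0, -0.6)]}[n]
    for i, (cx, cy) in enumerate(centers):
        ax.add_patch(plt.Circle((cx, cy), 1.0, alpha=0.3, label=f"replicate {i + 1}"))
    label_pos = {
        2: {(0,): (-1.0, 0), (1,): (1.0, 0), (0, 1): (0, 0)},
        3: {
            (0,): (-1.0, 0.6),
            (1,): (1.0, 0.6),
            (2,): (0, -1.2),
            (0, 1): (0, 0.6),
            (0, 2): (-0.6, -0.3),
            (1, 2): (0.6, -0.3),
            (0, 1, 2): (0, 0),
        },
    }[n]
    for subset, (x, y) in label_pos.items():
        ax.text(x, y, str(region_counts.get(subset, 0)), ha="center", va="center")
    ax.set_xlim(-2, 2)
    ax.set_ylim(-2, 2)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.legend(loc="upper right", fontsize=7)
    fig.savefig(path, dpi=120)
    plt.close(fig)
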