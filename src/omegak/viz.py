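"""Simple figure exports: k histogram, per-term k violins, GSEA bars."""

from __future__ import annotations

from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_k_histogram(k_values, path: str | Path, k_cut: float = 2.0) -> None:
    """Histogram of selection-intensity estimates below ``k_cut`` with
    the neutral k = 1 marked (values above the cut are counted in the
    title, mirroring the usual presentation)."""
    k = np.asarray(k_values, dtype=float)
    shown = k[k <= k_cut]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(shown, bins=40, color="#4878a8", edgecolor="white")
    ax.axvline(1.0, color="firebrick", lw=1.5)
    ax.set_xlabel("selection intensity k")
    ax.set_ylabel("orthogroups")
    ax.set_title(
        f"median k = {np.median(k):.3f} ({int((k > k_cut).sum())} above {k_cut:g} not shown)"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_go_k_violins(go_k_table, k_of: dict, go_map: dict, path: str | Path) -> None:
    """Violin plots of member k values for the deviating GO terms."""
    dev = go_k_table[go_k_table["deviant"]]
    if not len(dev):
        return
    data, labels = [], []
    for term in dev["term"]:
        ks = [k_of[og] for og, terms in go_map.items() if term in terms and og in k_of]
        data.append(ks)
        labels.append(term)
    fig, ax = plt.subplots(figsize=(max(4, 0.8 * len(data)), 4))
    ax.violinplot(data, showmedians=True)
    ax.axhline(1.0, color="firebrick", lw=1.0, ls="--")
    ax.set_xticks(range(1, len(labels) + 1), labels, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("k")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_gsea_top(results, path: str | Path, n: int = 10) -> None:
    """Horizontal bars of the top positive and negative NES gene sets."""
    from .stats import top_gene_sets

    pos, neg = top_gene_sets(results, n=n)
    rows = list(reversed(pos)) + list(neg)
    if not rows:
        return
    names = [r.gene_set for r in rows]
    nes = [r.nes for r in rows]
    colors = ["#2b6a99" if v > 0 else "#d9a441" for v in nes]
    fig, ax = plt.subplots(figsize=(6, max(3, 0.3 * len(rows))))
    ax.barh(range(len(rows)), nes, color=colors)
    ax.set_yticks(range(len(rows)), names, fontsize=7)
    ax.axvline(0, color="black", lw=0.8)
    ax.set_xlabel("normalised enrichment score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
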