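"""Minimal plot helpers: degree distributions and enrichment dotplots.

Matplotlib is imported lazily so the rest of the package stays importable
in plotting-free environments.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .compare import EnrichmentResult


def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def degree_distribution_plot(
    degrees_a: pd.Series,
    degrees_b: pd.Series,
    labels: tuple[str, str] = ("network A", "network B"),
    p_value: float | None = None,
    ax=None,
):
    """Side-by-side histograms of within-subgraph degrees in each network."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    bins = np.histogram_bin_edges(
        np.concatenate([degrees_a.values, degrees_b.values]), bins=20
    )
    ax.hist(degrees_a.values, bins=bins, alpha=0.6, label=labels[0])
    ax.hist(degrees_b.values, bins=bins, alpha=0.6, label=labels[1])
    ax.set_xlabel("weighted degree within subgraph")
    ax.set_ylabel("nodes")
    if p_value is not None:
        ax.set_title(f"Mann–Whitney p = {p_value:.2g}")
    ax.legend()
    return ax


def enrichment_dotplot(
    results: Sequence[EnrichmentResult] | Iterable[EnrichmentResult],
    top: int = 10,
    ax=None,
):
    """Dotplot of the top enriched sets: x = gene ratio, colour = adjusted p."""
    plt = _mpl()
    rows = sorted(results, key=lambda r: (r.adjusted_p, r.p_value))[:top]
    if not rows:
        raise ValueError("no enrichment results to plot")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * len(rows) + 1.5))
    y = np.arange(len(rows))[::-1]
    ratios = [r.gene_ratio for r in rows]
    sizes = [20 + 10 * r.overlap for r in rows]
    colors = [r.adjusted_p for r in rows]
    sc = ax.scatter(ratios, y, s=sizes, c=colors, cmap="viridis_r")
    ax.set_yticks(y)
    ax.set_yticklabels([r.set_name for r in rows])
    ax.set_xlabel("gene ratio")
    plt.colorbar(sc, ax=ax, label="adjusted p")
    return ax
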