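"""Minimal figures: ratio frequency curves and per-chromosome boxplots.

matplotlib is imported lazily so the core pipeline has no plotting
dependency.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .ratios import CANONICAL_RATIOS, RatioHistogram


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def ratio_curve(
    hists: Mapping[str, RatioHistogram],
    path,
    guides: Sequence[float] = (CANONICAL_RATIOS["inverse"], 1.0, 1.5),
) -> None:
    """Frequency-polygon plot of one or more ratio histograms."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, hist in hists.items():
        ax.plot(hist.centers, hist.frequencies, label=label, lw=1.5)
    for gx in guides:
        ax.axvline(gx, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("case / control expression ratio")
    ax.set_ylabel("frequency")
    if len(hists) > 1:
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def median_boxplot(table, path, biotype: str = "coding") -> None:
    """Boxplot of expression ratios per chromosome for one biotype."""
    plt = _mpl()
    sub = table[table["biotype"] == biotype]
    chroms = sorted(sub["chrom"].unique())
    data = [sub.loc[sub["chrom"] == c, "ratio"].to_numpy() for c in chroms]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(data, tick_labels=chroms, showfliers=False)
    ax.axhline(1.0, color="grey", ls="--", lw=0.8)
    for i, vals in enumerate(data, start=1):
        if len(vals):
            import numpy as np

            ax.text(i, ax.get_ylim()[1] * 0.97, f"{np.median(vals):.2f}", ha="center", fontsize=7)
    ax.set_ylabel("case / control expression ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
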