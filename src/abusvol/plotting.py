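"""Bland-Altman scatter plots."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .agreement import BlandAltmanResult, PairedMeasurements


def bland_altman_plot(
    pairs: PairedMeasurements,
    result: BlandAltmanResult,
    ax=None,
    title: str | None = None,
    out: str | Path | None = None,
):
    """Plot per-pair mean vs difference with bias and limits of agreement.

    Points outside the limits are highlighted. Returns the axes; saves
    to ``out`` (PNG/SVG by extension) when given.
    """
    import matplotlib

    if out is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    means = (pairs.a + pairs.b) / 2
    diffs = pairs.differences
    outside = np.array([lbl in result.outside_indices for lbl in pairs.labels])
    ax.scatter(means[~outside], diffs[~outside], s=25, color="tab:blue")
    if outside.any():
        ax.scatter(
            means[outside], diffs[outside], s=35, color="tab:red",
            label="outside limits",
        )
        ax.legend(frameon=False)
    ax.axhline(result.bias, color="k", lw=1)
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.annotate(
        f"bias = {result.bias:.4f}",
        xy=(0.02, 0.95), xycoords="axes fraction", fontsize=8,
    )
    ax.set_xlabel("mean of paired measurements (cm³)")
    ax.set_ylabel("difference (cm³)")
    if title:
        ax.set_title(title)
    if out is not None:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
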