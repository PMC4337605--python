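"""Histogram plots with Gaussian overlays (headless-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .helixmetrics import DistributionSummary, summarize

__all__ = ["plot_distribution"]


def plot_distribution(
    values,
    path,
    xlabel: str = "half helical pitch (nm)",
    bin_width: float = 1.0,
    summary: DistributionSummary | None = None,
) -> DistributionSummary:
    """Histogram with the maximum-likelihood Gaussian drawn over +/-3 sigma.

    Returns the summary used for the overlay.
    """
    v = np.asarray(values, dtype=float)
    if summary is None:
        summary = summarize(v)
    lo, hi = summary.fit_range
    bins = np.arange(min(lo, v.min()), max(hi, v.max()) + bin_width, bin_width)
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.hist(v, bins=bins, color="0.7", edgecolor="0.4")
    x = np.linspace(lo, hi, 300)
    scale = v.size * bin_width
    pdf = np.exp(-0.5 * ((x - summary.gauss_mu) / summary.gauss_sigma) ** 2) / (
        summary.gauss_sigma * np.sqrt(2 * np.pi)
    )
    ax.plot(x, scale * pdf, "k-", lw=1.5)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("count")
    ax.set_title(f"n={summary.n}  mean={summary.mean:.1f}  sd={summary.sd:.1f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return summary
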