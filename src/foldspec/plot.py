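"""Minimal plotting helpers for profiles and binned trends."""

from __future__ import annotations

import numpy as np

from .metagene import MetaGeneProfile
from .stats import TrendResult

__all__ = ["plot_metagene_profile", "plot_binned_trend"]


def plot_metagene_profile(profile: MetaGeneProfile, ax=None, min_genes: int = 3,
                          label: str | None = None, color=None):
    """Mean ± SE ribbon against offset; offsets with few genes are masked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots()
    show = profile.n_genes >= min_genes
    x = profile.offsets[show]
    m = profile.mean[show]
    se = profile.se[show]
    (line,) = ax.plot(x, m, label=label, color=color)
    ok = np.isfinite(se)
    ax.fill_between(x[ok], (m - se)[ok], (m + se)[ok], alpha=0.25,
                    color=line.get_color())
    ax.axhline(1.0, color="k", linestyle="--", linewidth=0.8)
    ax.set_xlabel("offset from focal site (nt)")
    ax.set_ylabel("mean signal")
    return ax


def plot_binned_trend(trend: TrendResult, ax=None, label: str | None = None):
    """Bin means ± SE against bin rank, annotated with the unbinned SCC."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots()
    x = np.arange(1, len(trend.bin_means) + 1)
    ax.errorbar(x, trend.bin_means, yerr=trend.bin_se, fmt="o-", capsize=2, label=label)
    ax.set_xlabel("rank bin")
    ax.set_ylabel("mean y")
    ax.set_title(f"SCC = {trend.rho:.3g}")
    return ax
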