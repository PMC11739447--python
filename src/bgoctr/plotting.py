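"""Optional figures: timing histograms with fitted kernel components,
violin summaries of the bootstrap metrics, and the estimator-difference
scatter.  Requires matplotlib (the ``plot`` extra); imported lazily so
the analysis stack works without it.
"""

from __future__ import annotations

import numpy as np

from .ctr import CtrReport, KernelFit, METRICS


def _mpl():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_timing_histogram(values: np.ndarray, kernel: KernelFit, path: str,
                          title: str = "") -> None:
    """Histogram of timing values with the fitted kernel and its two
    Gaussian components overlaid."""
    plt = _mpl()
    values = np.asarray(values, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    counts, edges, _ = ax.hist(values, bins=100, color="0.8",
                               label=f"data (n={values.size})")
    bw = edges[1] - edges[0]
    x = np.linspace(edges[0], edges[-1], 1000)
    scale = kernel.N * bw
    z = (x - kernel.mu)
    narrow = (scale * kernel.r_c / (np.sqrt(2 * np.pi) * kernel.sigma_c)
              * np.exp(-0.5 * (z / kernel.sigma_c) ** 2))
    broad = (scale * (1 - kernel.r_c) / (np.sqrt(2 * np.pi) * kernel.sigma_s)
             * np.exp(-0.5 * (z / kernel.sigma_s) ** 2))
    ax.plot(x, narrow + broad, "k-", label="fit")
    ax.plot(x, narrow, "--", label=f"narrow ($\\sigma_C$={kernel.sigma_c:.0f} ps)")
    ax.plot(x, broad, "-.", label=f"broad ($\\sigma_S$={kernel.sigma_s:.0f} ps)")
    ax.set_xlabel("coincidence time delay (ps)")
    ax.set_ylabel("events / bin")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_metric_violins(report: CtrReport, path: str) -> None:
    """Violin plots of the per-resample CTR metrics per method."""
    plt = _mpl()
    methods = list(report.summary)
    fig, axes = plt.subplots(1, len(METRICS), figsize=(4 * len(METRICS), 4),
                             sharex=True)
    for ax, metric in zip(np.atleast_1d(axes), METRICS):
        data = [report.per_resample[f"{m}_{metric}"].to_numpy()
                for m in methods]
        ax.violinplot(data, showmeans=True)
        ax.set_xticks(range(1, len(methods) + 1), methods)
        ax.set_title(metric)
        ax.set_ylabel("ps")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_difference_scatter(diffs, path: str) -> None:
    """LED-CNN vs LED-TWC per-event differences with marginals."""
    plt = _mpl()
    x = diffs["led_minus_twc"].to_numpy()
    y = diffs["led_minus_cnn"].to_numpy()
    fig, axes = plt.subplots(2, 2, figsize=(6, 6), sharex="col", sharey="row",
                             gridspec_kw={"width_ratios": [4, 1],
                                          "height_ratios": [1, 4]})
    axes[0, 1].axis("off")
    axes[1, 0].plot(x, y, ".", ms=2, alpha=0.4)
    lim = max(np.abs(np.concatenate([x, y])))
    axes[1, 0].plot([-lim, lim], [-lim, lim], "k--", lw=0.8)
    axes[1, 0].set_xlabel("LED $-$ TWC (ps)")
    axes[1, 0].set_ylabel("LED $-$ CNN (ps)")
    axes[0, 0].hist(x, bins=80)
    axes[1, 1].hist(y, bins=80, orientation="horizontal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
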