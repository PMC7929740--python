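"""Figure helpers: component effect curves, FoSR coefficients, strata means."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

_HOURS = np.arange(0, 25, 4)


def _hour_axis(ax, minutes):
    ax.set_xlim(0, 1440)
    ax.set_xticks(_HOURS * 60)
    ax.set_xticklabels([f"{h:02d}:00" for h in _HOURS])
    ax.set_xlabel("time of day")


def plot_component_effects(fpca_results, path=None):
    """Mean daily activity with +/- 1 score-SD excursions per component."""
    K = fpca_results.n_retained
    fig, axes = plt.subplots(1, K, figsize=(4 * K, 3.2), squeeze=False)
    t = fpca_results.basis.minute_grid()
    for k in range(1, K + 1):
        ax = axes[0][k - 1]
        c = fpca_results.effect_curves(k)
        ax.plot(t, c["mean"], color="black", label="mean")
        ax.plot(t, c["plus"], color="tab:red", label="+1 SD")
        ax.plot(t, c["minus"], color="tab:blue", label="-1 SD")
        pct = fpca_results.variance_proportions[k - 1]
        ax.set_title(f"component {k} ({pct:.1%})")
        _hour_axis(ax, t)
        if k == 1:
            ax.set_ylabel("activity")
            ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_fosr_coefficients(fosr_results, covariates=None, path=None, level=0.95):
    """beta_j(t) with pointwise bands, one panel per covariate."""
    names = covariates or fosr_results.columns[1:]
    n = len(names)
    ncol = min(4, n)
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(3.6 * ncol, 2.8 * nrow), squeeze=False
    )
    tests = fosr_results.global_tests().set_index("covariate")
    for i, name in enumerate(names):
        ax = axes[i // ncol][i % ncol]
        beta = fosr_results.coefficient_function(name)
        lo, hi = fosr_results.pointwise_bands(name, level)
        ax.fill_between(fosr_results.grid, lo, hi, alpha=0.25)
        ax.plot(fosr_results.grid, beta)
        ax.axhline(0.0, color="grey", lw=0.7)
        p = tests.loc[name, "p"]
        stars = "**" if p < 0.01 else ("*" if p < 0.05 else "")
        ax.set_title(f"{name} {stars}", fontsize=9)
        _hour_axis(ax, fosr_results.grid)
    for j in range(n, nrow * ncol):
        axes[j // ncol][j % ncol].axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_stratified_means(subject_table, Y, grid, by, path=None, bins=None):
    """Average diurnal curves stratified by a subject-level variable."""
    tab = subject_table.copy()
    if bins is not None:
        tab["_stratum"] = bins(tab[by])
    else:
        tab["_stratum"] = tab[by]
    fig, ax = plt.subplots(figsize=(5.5, 3.4))
    for level, idx in tab.groupby("_stratum").groups.items():
        pos = tab.index.get_indexer(idx)
        ax.plot(grid, Y[pos].mean(axis=0), label=str(level))
    _hour_axis(ax, grid)
    ax.set_ylabel("activity")
    ax.legend(frameon=False, fontsize=8, title=by)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
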