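"""Figure helpers: reaction norms, BLUP histograms, selection dot-and-interval
plots, marginal prediction panels and posterior predictive checks."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def blup_histograms(blups: pd.DataFrame, path=None):
    """Histograms of reported reaction-norm intercepts and slopes."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    axes[0].hist(blups["reported_intercept"], bins=30, color="#4878a8")
    axes[0].axvline(blups["reported_intercept"].mean(), ls="--", c="k")
    axes[0].set_xlabel("reaction-norm intercept (days after equinox)")
    if "reported_slope" in blups:
        axes[1].hist(blups["reported_slope"], bins=30, color="#a85448")
        axes[1].axvline(blups["reported_slope"].mean(), ls="--", c="k")
        axes[1].set_xlabel("reaction-norm slope (days / degC)")
    for ax in axes:
        ax.set_ylabel("individuals")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return fig


def reaction_norm_lines(blups: pd.DataFrame, climate: pd.DataFrame, path=None):
    """Per-individual predicted reaction norms over the observed temperature range."""
    fig, ax = plt.subplots(figsize=(6, 4))
    tr = np.array([climate["april_mean_centred"].min(), climate["april_mean_centred"].max()])
    slopes = blups.get("reported_slope")
    if slopes is None:
        raise ValueError("need slope BLUPs to draw reaction norms")
    order = np.argsort(slopes.to_numpy())
    cmap = plt.get_cmap("viridis")
    for rank, i in enumerate(order):
        c = cmap(rank / max(len(order) - 1, 1))
        ax.plot(tr, blups["reported_intercept"].iloc[i] + slopes.iloc[i] * tr,
                color=c, lw=0.4, alpha=0.5)
    ax.plot(tr, blups["reported_intercept"].mean() + slopes.mean() * tr, "k-", lw=2.5)
    ax.set_xlabel("mean-centred April temperature (degC)")
    ax.set_ylabel("first flowering day (days after equinox)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return fig


def selection_dot_interval(tables: dict[str, pd.DataFrame], path=None):
    """Dot-and-HPD-interval plot of selection differentials and gradients.

    ``tables`` maps a label (e.g. the fitness measure) to a SelectionSummary
    table with columns coefficient / posterior_mode / hpd_low / hpd_high.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    labels = []
    ypos = 0
    colors = {0: "k", 1: "0.5", 2: "tab:blue", 3: "tab:orange"}
    all_coefs = list(dict.fromkeys(
        c for t in tables.values() for c in t["coefficient"]
    ))
    for coef in all_coefs:
        for j, (lab, tab) in enumerate(tables.items()):
            row = tab[tab["coefficient"] == coef]
            if row.empty:
                continue
            r = row.iloc[0]
            y = ypos - 0.15 * j
            ax.errorbar([r["posterior_mode"]], [y],
                        xerr=[[r["posterior_mode"] - r["hpd_low"]],
                              [r["hpd_high"] - r["posterior_mode"]]],
                        fmt="o", color=colors.get(j, "k"),
                        label=lab if coef == all_coefs[0] else None)
        labels.append(coef)
        ypos += 1
    ax.axvline(0, ls=":", c="0.6")
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(labels)
    ax.set_xlabel("selection coefficient (latent log-fitness scale)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return fig


def prediction_panels(pred: pd.DataFrame, path=None):
    """Probability of any seeds vs plasticity, one panel per temperature."""
    temps = sorted(pred["april_temp"].unique())
    fig, axes = plt.subplots(1, len(temps), figsize=(3 * len(temps), 3.2),
                             sharey=True, squeeze=False)
    for ax, tv in zip(axes[0], temps):
        sub = pred[pred["april_temp"] == tv]
        ax.plot(sub["plasticity"], sub["p_any_seeds"], "k-")
        ax.fill_between(sub["plasticity"], sub["hpd_low"], sub["hpd_high"],
                        alpha=0.25, color="tab:blue")
        ax.set_title(f"April T = {tv:+.2f} degC", fontsize=9)
        ax.set_xlabel("plasticity (residual slope)")
    axes[0][0].set_ylabel("P(any seeds)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return fig


def ppc_histogram(observed: np.ndarray, replicated: np.ndarray, label: str, path=None):
    """Posterior predictive check: observed vs replicated distributions."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    bins = np.histogram_bin_edges(observed, bins=30)
    for rep in replicated[: min(len(replicated), 30)]:
        ax.hist(rep, bins=bins, histtype="step", color="tab:blue", alpha=0.2,
                density=True)
    ax.hist(observed, bins=bins, histtype="step", color="k", lw=2, density=True)
    ax.set_xlabel(label)
    ax.set_ylabel("density")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return fig
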