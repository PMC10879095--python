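"""Basic figure exports: Kaplan-Meier curves, meta forest plot, consensus heatmap."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .survival_eval import MetaResult, km_curves

__all__ = ["km_plot", "forest_plot", "consensus_heatmap"]


def km_plot(groups, survival, path, title: str = "") -> None:
    curves = km_curves(groups, survival)
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, df in curves.items():
        ax.step(df.index, df["survival"], where="post", label=label)
        ax.fill_between(df.index, df["ci_lower"], df["ci_upper"],
                        step="post", alpha=0.2)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def forest_plot(meta: MetaResult, path) -> None:
    df = meta.to_frame()
    fig, ax = plt.subplots(figsize=(5, 0.5 * len(df) + 1.5))
    y = np.arange(len(df))[::-1]
    hr = np.exp(df["log_hr"])
    lo = np.exp(df["log_hr"] - 1.96 * df["se"])
    hi = np.exp(df["log_hr"] + 1.96 * df["se"])
    ax.errorbar(hr, y, xerr=[hr - lo, hi - hr], fmt="s", color="k")
    ax.axvline(meta.fixed_hr, color="tab:blue", ls="--",
               label=f"fixed HR {meta.fixed_hr:.2f}")
    ax.axvline(1.0, color="grey", lw=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels(df.index)
    ax.set_xlabel("hazard ratio")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def consensus_heatmap(consensus, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(np.asarray(consensus), vmin=0, vmax=1, cmap="Blues")
    fig.colorbar(im, ax=ax, label="consensus")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
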