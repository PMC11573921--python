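"""Static figures: coefficient spread, fairness-ranking panels, importance bars."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")  # headless export only
import matplotlib.pyplot as plt  # noqa: E402


def coefficient_violin(irs, path=None):
    """Distribution of each coefficient across the near-optimal models."""
    frame = irs.to_frame()
    cols = [c for c in frame.columns if c.startswith("beta:")]
    data = [frame[c].dropna().to_numpy() for c in cols]
    fig, ax = plt.subplots(figsize=(max(6, 0.7 * len(cols)), 4))
    ax.violinplot([d for d in data if len(d)], showmedians=True)
    ax.set_xticks(range(1, len(cols) + 1))
    ax.set_xticklabels([c[5:] for c in cols], rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("coefficient")
    ax.set_title(f"Coefficient spread across {irs.size} near-optimal models")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def ranking_panels(ranked, path=None, highlight_top: int = 10):
    """One scatter panel per fairness metric, ordered by FRI rank."""
    metrics = ("equal_opportunity", "equalized_odds", "ber_equality")
    ranks = np.array([r.rank for r in ranked])
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
    for ax, m in zip(axes, metrics):
        vals = np.array([getattr(r.profile, m) for r in ranked])
        ax.scatter(ranks, vals, s=6, alpha=0.4, color="steelblue")
        top = ranks <= highlight_top
        ax.scatter(ranks[top], vals[top], s=18, color="goldenrod", label=f"top {highlight_top}")
        ax.set_xlabel("FRI rank")
        ax.set_title(m.replace("_", " "))
    axes[0].set_ylabel("metric value")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def importance_bars(table, path=None):
    """Paired horizontal bars: baseline vs fairness-aware mean |SHAP|."""
    y = np.arange(len(table))
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(table) + 1.5))
    ax.barh(y + 0.2, table["baseline_importance"], height=0.4, label="baseline", color="gray")
    ax.barh(y - 0.2, table["faim_importance"], height=0.4, label="fairness-aware", color="seagreen")
    ax.set_yticks(y)
    ax.set_yticklabels(table["variable"])
    ax.invert_yaxis()
    ax.set_xlabel("mean |SHAP| (log-odds scale)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
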