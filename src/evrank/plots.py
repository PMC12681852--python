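"""Plot artifacts: score bar chart, normalized-factor view, radar, 3D view.

Content contracts only (series counts, orderings, axis quantities); styling
is intentionally minimal matplotlib.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")  # noqa: E402  (headless by default)
import matplotlib.pyplot as plt  # noqa: E402

from .exceptions import ValidationError

__all__ = ["plot_scores", "plot_normalized", "plot_radar", "plot_decision_space"]


def plot_scores(results, ax=None):
    """Overall weighted score per alternative, bars sorted descending."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    tab = results.table
    ax.bar(tab.index, tab["score"], color="#3b6ea5")
    ax.set_ylabel("weighted score")
    ax.set_ylim(0, 1.05)
    ax.set_title("Overall therapeutic-potential score")
    ax.tick_params(axis="x", rotation=45)
    for lbl in ax.get_xticklabels():
        lbl.set_horizontalalignment("right")
    ax.figure.tight_layout()
    return ax


def plot_normalized(results, ax=None):
    """Grouped per-factor normalized values across all alternatives."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4.5))
    n = results.normalized
    k = len(n.factor_names)
    n_alt = len(n.alternatives)
    x = np.arange(k, dtype=float)
    width = 0.8 / n_alt
    for i, alt in enumerate(n.alternatives):
        ax.bar(x + (i - n_alt / 2) * width + width / 2,
               n.values.loc[alt].to_numpy(), width, label=alt)
    ax.set_xticks(x)
    ax.set_xticklabels(n.factor_names, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("normalized value")
    ax.set_title("Factor normalization")
    ax.legend(fontsize=6, ncol=2)
    ax.figure.tight_layout()
    return ax


def plot_radar(results, top_k: int = 3, ax=None):
    """Radar (spider) chart of the top-k ranked alternatives over all factors."""
    n_alt = len(results.matrix.alternatives)
    if not 1 <= top_k <= n_alt:
        raise ValidationError(f"top_k must be in [1, {n_alt}], got {top_k}")
    if ax is None:
        fig = plt.figure(figsize=(6, 6))
        ax = fig.add_subplot(111, polar=True)
    names = results.normalized.factor_names
    angles = np.linspace(0, 2 * np.pi, len(names), endpoint=False)
    closed = np.concatenate([angles, angles[:1]])
    for alt in results.top(top_k):
        vals = results.normalized.values.loc[alt].to_numpy()
        ax.plot(closed, np.concatenate([vals, vals[:1]]), label=alt)
        ax.fill(closed, np.concatenate([vals, vals[:1]]), alpha=0.15)
    ax.set_xticks(angles)
    ax.set_xticklabels(names, fontsize=6)
    ax.set_ylim(0, 1)
    ax.set_title(f"Top-{top_k} factor comparison")
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=7)
    ax.figure.tight_layout()
    return ax


def plot_decision_space(results, ax=None):
    """3D scatter of (weighted score, closeness to ideal, rank)."""
    if ax is None:
        fig = plt.figure(figsize=(6.5, 5.5))
        ax = fig.add_subplot(111, projection="3d")
    tab = results.table
    ax.scatter(tab["score"], tab["closeness"], tab["rank"],
               c=tab["rank"], cmap="viridis_r", s=60, depthshade=False)
    for alt, row in tab.iterrows():
        ax.text(row["score"], row["closeness"], row["rank"], alt, fontsize=6)
    ax.set_xlabel("weighted score")
    ax.set_ylabel("closeness to ideal")
    ax.set_zlabel("rank")
    ax.invert_zaxis()
    ax.set_title("Decision space (best/worst-case proximity)")
    return ax
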