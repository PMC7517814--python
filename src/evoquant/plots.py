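"""Dot-interval and eigenstructure figures.

Figures are regenerated purely from results objects / tidy tables, never
from hidden state.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_response_intervals", "plot_eigen_summary"]


def plot_response_intervals(pred, components=("total",), ax=None,
                            observed_marker: str = "^"):
    """Dot-and-interval panel of predicted responses (posterior mean and
    95% HPD per trait), with observed changes overlaid as triangles.

    Parameters
    ----------
    pred : ResponsePrediction
    components : which components to draw ("total", "direct", "indirect")
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * len(pred.trait_names) + 1))
    names = pred.trait_names
    y = np.arange(len(names))[::-1]
    offsets = np.linspace(-0.2, 0.2, len(components)) if \
        len(components) > 1 else [0.0]
    colors = {"total": "black", "direct": "tab:blue",
              "indirect": "tab:orange"}
    for comp, off in zip(components, offsets):
        tab = pred.component(comp).loc[names]
        ax.hlines(y + off, tab["hpd_lo"], tab["hpd_hi"],
                  color=colors.get(comp, "gray"), lw=1.5, label=comp)
        ax.plot(tab["mean"], y + off, "o", color=colors.get(comp, "gray"),
                ms=4)
    if pred.observed is not None:
        ax.plot(pred.observed.loc[names], y, observed_marker,
                color="tab:green", ms=7, label="observed")
    ax.axvline(0.0, color="gray", lw=0.8, ls=":")
    ax.set_yticks(y)
    ax.set_yticklabels(names)
    ax.set_xlabel("response (parental phenotypic SD)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_eigen_summary(summaries: dict, axis=0, n_pcs: int = 5, axes=None):
    """Eigenvalue sizes, PC1 relative contribution, and PC-vs-trait-axis
    angles for a set of named G-matrices (e.g. the three selection lines).

    Parameters
    ----------
    summaries : mapping name -> EigenSummary
    axis : trait axis (index or name) for the angle panel
    """
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    ax_val, ax_rel, ax_ang = axes
    width = 0.8 / len(summaries)
    for k, (name, summ) in enumerate(summaries.items()):
        x = np.arange(min(n_pcs, summ.values.size))
        ax_val.bar(x + k * width, summ.values[: len(x)], width, label=name)
        ax_rel.bar([k], [summ.relative[0]], 0.6, label=name)
        angles = summ.axis_angles(axis)[: len(x)]
        ax_ang.plot(x + 1, angles, "o-", label=name)
    ax_val.set_xlabel("PC")
    ax_val.set_ylabel("eigenvalue")
    ax_rel.set_ylabel("PC1 / sum of PCs")
    ax_rel.set_xticks(range(len(summaries)))
    ax_rel.set_xticklabels(list(summaries), rotation=45)
    ax_ang.set_xlabel("PC")
    ax_ang.set_ylabel("angle with trait axis (deg)")
    ax_ang.set_ylim(0, 95)
    ax_val.legend(frameon=False, fontsize=8)
    return axes
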