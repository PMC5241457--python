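"""Dartboard similarity plots and null-distribution histograms."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .validation import NullDistributions


@dataclass
class DartboardLayout:
    """Radial layout: reference subject at the center, others on rays.

    Radii are proportional to the distance from the center subject
    (scaled so the farthest subject sits on the outer ring); angles are
    equally spaced in subject order.  The nearest same-group and nearest
    other-group subjects are flagged for highlighting.
    """

    center: str
    subjects: list[str]
    radii: np.ndarray
    angles: np.ndarray
    groups: np.ndarray
    nearest_same: str | None
    nearest_other: str | None


def dartboard_coordinates(distances: pd.Series,
                          center: str,
                          groups: pd.Series,
                          outer_radius: float = 1.0) -> DartboardLayout:
    """Lay out subjects around a reference subject by behavioral distance.

    ``distances`` maps each non-center subject to its distance from the
    center subject; the layout is invariant to rescaling all distances.
    """
    if center in distances.index:
        distances = distances.drop(center)
    if len(distances) == 0:
        raise ValueError("no subjects to place on the dartboard")
    subjects = list(distances.index)
    values = distances.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("distances must be non-negative")
    max_d = values.max()
    radii = (values / max_d * outer_radius if max_d > 0
             else np.zeros_like(values))
    angles = np.arange(len(subjects)) * 2 * np.pi / len(subjects)
    grp = groups.loc[subjects].to_numpy()
    center_group = groups.loc[center]
    nearest_same = nearest_other = None
    same = [i for i, g in enumerate(grp) if g == center_group]
    other = [i for i, g in enumerate(grp) if g != center_group]
    if same:
        nearest_same = subjects[min(same, key=lambda i: values[i])]
    if other:
        nearest_other = subjects[min(other, key=lambda i: values[i])]
    return DartboardLayout(center=center, subjects=subjects, radii=radii,
                           angles=angles, groups=grp,
                           nearest_same=nearest_same,
                           nearest_other=nearest_other)


_GROUP_COLORS = {0: "tab:blue", 1: "tab:red"}


def plot_dartboard(layout: DartboardLayout,
                   projected_group: int | None = None,
                   n_rings: int = 5,
                   path: str | Path | None = None) -> plt.Figure:
    """Render a dartboard layout with equally spaced reference rings."""
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"},
                           figsize=(5, 5))
    ax.set_yticks(np.linspace(0, 1, n_rings + 1)[1:])
    ax.set_yticklabels([])
    ax.set_xticks([])
    if projected_group is not None:
        ax.set_facecolor(_GROUP_COLORS.get(projected_group, "white"))
        ax.patch.set_alpha(0.12)
    for subject, radius, angle, group in zip(layout.subjects, layout.radii,
                                             layout.angles, layout.groups):
        color = _GROUP_COLORS.get(int(group), "gray")
        ax.plot(angle, radius, "o", color=color, markersize=7)
        if subject == layout.nearest_same:
            ax.plot(angle, radius, "o", mfc="none", mec="green",
                    markersize=14, mew=2)
        if subject == layout.nearest_other:
            ax.plot(angle, radius, "o", mfc="none", mec="black",
                    markersize=14, mew=2)
    ax.plot(0, 0, "*", color="goldenrod", markersize=16, zorder=5)
    ax.set_title(f"reference: {layout.center}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_null_distributions(nd: NullDistributions,
                            path: str | Path | None = None) -> plt.Figure:
    """Histogram per d^{gg'} statistic, dashed line at the observed value."""
    stats = list(nd.observed)
    ncols = 4
    nrows = int(np.ceil(len(stats) / ncols))
    fig, axes = plt.subplots(nrows, ncols,
                             figsize=(3.2 * ncols, 2.6 * nrows),
                             squeeze=False)
    for ax, stat in zip(axes.flat, stats):
        ax.hist(nd.null[stat], bins=20, color="lightsteelblue",
                edgecolor="white")
        ax.axvline(nd.observed[stat], color="black", linestyle="--")
        ax.set_title(stat, fontsize=9)
    for ax in axes.flat[len(stats):]:
        ax.axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
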