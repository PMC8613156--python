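"""Figures: RI curves, adjusted R^2 per frame, permutation box plots.

Convention: solid lines for the control (reference) group, dashed for the
treatment group(s), one panel per feature.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .inference import PermutationResult
from .model import RICurveSet


def plot_ri_curves(ri: RICurveSet, path=None):
    """One panel per feature, weight against frame, one line per group."""
    if not ri.curves:
        raise ValueError("no fitted frames to plot")
    groups = list(ri.curves)
    features = list(ri.curves[groups[0]].columns)
    fig, axes = plt.subplots(
        len(features), 1, figsize=(7, 1.8 * len(features)), sharex=True, squeeze=False
    )
    for ax, feat in zip(axes[:, 0], features):
        for gi, g in enumerate(groups):
            is_ref = gi == len(groups) - 1
            df = ri.curves[g]
            ax.plot(
                df.index, df[feat],
                linestyle="-" if is_ref else "--",
                label=g,
            )
        ax.set_ylabel(feat, fontsize=8)
        ax.axhline(0.0, color="0.8", lw=0.5)
    axes[0, 0].legend(fontsize=8)
    axes[-1, 0].set_xlabel("frame")
    fig.suptitle("relative importance" + (" (normalized)" if ri.normalized else ""))
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_r2(r2_by_frame, path=None):
    """Adjusted R^2 against frame."""
    fig, ax = plt.subplots(figsize=(7, 2.5))
    ax.plot(r2_by_frame.index, r2_by_frame.to_numpy(), marker=".")
    ax.set_xlabel("frame")
    ax.set_ylabel("adjusted $R^2$")
    ax.set_ylim(min(0.0, float(r2_by_frame.min()) - 0.05), 1.0)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_permutation_boxes(results: list[PermutationResult], path=None):
    """Permutation distributions per feature/frame with the observed value marked."""
    done = [r for r in results if not r.skipped]
    if not done:
        raise ValueError("no permutation results to plot")
    features = list(done[0].observed)
    fig, axes = plt.subplots(
        len(features), 1, figsize=(7, 2.0 * len(features)), sharex=True, squeeze=False
    )
    for ax, feat in zip(axes[:, 0], features):
        data = [r.permuted[feat][np.isfinite(r.permuted[feat])] for r in done]
        pos = np.arange(len(done))
        ax.boxplot(data, positions=pos, widths=0.6)
        ax.scatter(pos, [r.observed[feat] for r in done], marker="x", color="red", zorder=3)
        ax.set_ylabel(feat, fontsize=8)
        ax.set_xticks(pos)
        ax.set_xticklabels([str(r.frame_index) for r in done], fontsize=7)
    axes[-1, 0].set_xlabel("frame")
    fig.suptitle("group-difference coefficients under permutation")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
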