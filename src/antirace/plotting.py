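"""Publication-style figures for the standard analyses."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first
import matplotlib.pyplot as plt


def plot_group_delta(x_mean, y_mean, y_se=None, label=None, ax=None):
    """Six-point delta plot with standard-error bars.

    Positive y is antisaccade slowing relative to prosaccades; a negative
    slope indicates conflict resolved over time.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(x_mean, y_mean, yerr=y_se, marker="o", capsize=3, label=label)
    ax.axhline(0.0, color="0.6", lw=0.8, zorder=0)
    ax.set_xlabel("mean RT (s)")
    ax.set_ylabel("anti − pro RT (s)")
    if label:
        ax.legend(frameon=False)
    return ax


def plot_confusion(confusion, classes, ax=None, normalize=True):
    """Row-normalized confusion matrix of a multiclass staging classifier."""
    confusion = np.asarray(confusion, dtype=float)
    if normalize:
        confusion = confusion / confusion.sum(axis=1, keepdims=True)
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(confusion, cmap="Blues", vmin=0, vmax=confusion.max())
    ax.set_xticks(range(len(classes)), classes)
    ax.set_yticks(range(len(classes)), classes)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(confusion.shape[0]):
        for j in range(confusion.shape[1]):
            ax.text(j, i, f"{confusion[i, j]:.2f}", ha="center", va="center",
                    color="white" if confusion[i, j] > 0.5 * confusion.max() else "black")
    ax.figure.colorbar(im, ax=ax, fraction=0.046)
    return ax
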