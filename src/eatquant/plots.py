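"""Agreement plots: regression, kernel-density and Bland–Altman panels."""

from __future__ import annotations

import os
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluate import bland_altman, pearson_r


def regression_plot(labels: Sequence[float], preds: Sequence[float],
                    path: str | os.PathLike, quantity: str = "EATv (mL)") -> None:
    labels = np.asarray(labels, float)
    preds = np.asarray(preds, float)
    pr = pearson_r(labels, preds)
    fig, ax = plt.subplots(figsize=(4.2, 4))
    ax.scatter(labels, preds, s=18, alpha=0.7)
    lim = [min(labels.min(), preds.min()), max(labels.max(), preds.max())]
    ax.plot(lim, lim, "k--", lw=1)
    ax.set_xlabel(f"label {quantity}")
    ax.set_ylabel(f"predicted {quantity}")
    ax.set_title(f"r = {pr.r:.3f} (R² = {pr.r_squared:.3f})")
    fig.tight_layout()
    fig.savefig(os.fspath(path), dpi=120)
    plt.close(fig)


def density_plot(labels: Sequence[float], preds: Sequence[float],
                 path: str | os.PathLike, quantity: str = "EATv (mL)") -> None:
    from scipy import stats

    labels = np.asarray(labels, float)
    preds = np.asarray(preds, float)
    grid = np.linspace(min(labels.min(), preds.min()), max(labels.max(), preds.max()), 200)
    fig, ax = plt.subplots(figsize=(4.6, 3.4))
    for vals, name in ((labels, "label"), (preds, "predicted")):
        ax.plot(grid, stats.gaussian_kde(vals)(grid), label=name)
        ax.axvline(vals.mean(), ls="--", lw=1)
    ax.set_xlabel(quantity)
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(os.fspath(path), dpi=120)
    plt.close(fig)


def bland_altman_plot(labels: Sequence[float], preds: Sequence[float],
                      path: str | os.PathLike, quantity: str = "EATv (mL)") -> None:
    labels = np.asarray(labels, float)
    preds = np.asarray(preds, float)
    ba = bland_altman(labels, preds)
    mean_ab = (labels + preds) / 2
    diff = preds - labels
    fig, ax = plt.subplots(figsize=(4.6, 3.4))
    ax.scatter(mean_ab, diff, s=18, alpha=0.7)
    ax.axhline(ba.mean_diff, color="k", lw=1)
    for y in (ba.loa_low, ba.loa_high):
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.set_xlabel(f"mean of label and predicted {quantity}")
    ax.set_ylabel(f"predicted − label {quantity}")
    ax.set_title(f"mean diff {ba.mean_diff:.2f}, LoA [{ba.loa_low:.2f}, {ba.loa_high:.2f}]")
    fig.tight_layout()
    fig.savefig(os.fspath(path), dpi=120)
    plt.close(fig)
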