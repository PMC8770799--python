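"""Diagnostic plots: training curves, calibration, example field-seasons."""

from __future__ import annotations

import numpy as np

from .evaluate import calibration_curve

__all__ = ["plot_history", "plot_calibration", "plot_field"]


def plot_history(results, ax=None):
    """Training (and validation) loss per epoch for a fitted detector."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    h = results.history
    ax.plot(h["train_loss"], label="train BCE")
    if h.get("val_loss"):
        ax.plot(h["val_loss"], label="validation BCE")
        ax.axvline(results.best_epoch, ls=":", color="grey", label="best epoch")
    ax.set_xlabel("epoch")
    ax.set_ylabel("binary cross-entropy")
    ax.legend()
    return ax


def plot_calibration(scores, flags, n_bins: int = 10, ax=None):
    """Reliability diagram of season scores against observed mown fractions."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    mean_pred, observed, count = calibration_curve(scores, flags, n_bins)
    occupied = count > 0
    ax.plot([0, 1], [0, 1], ls="--", color="grey", label="perfect calibration")
    ax.plot(mean_pred[occupied], observed[occupied], marker="o", label="model")
    ax.set_xlabel("mean predicted season score")
    ax.set_ylabel("observed mown fraction")
    ax.legend()
    return ax


def plot_field(grid, probs=None, event_starts=None, ax=None):
    """One field-season: channels on the daily grid, optional probabilities."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    days = np.arange(grid.n_days)
    ax.plot(days, grid.ndvi, color="green", label="ndvi")
    ax.plot(days, grid.cohvv_sm, color="black", label="cohvv_sm")
    ax.plot(days, grid.cohvh_sm, color="blue", label="cohvh_sm")
    if probs is not None:
        ax.plot(days, probs, color="red", alpha=0.7, label="P(mowing)")
    if event_starts is not None:
        for s in event_starts:
            ax.axvline(s, color="orange", ls=":")
    ax.set_xlabel("day of season")
    ax.legend()
    return ax
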