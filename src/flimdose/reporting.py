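"""Tabular and graphical report helpers.

Score tables and importance reports go to plain CSV; the optional figures
are the three standard diagnostics of the pipeline: predicted-vs-actual
scatter for one split, predictions sorted by target, and the training
convergence curves of a neural fold.  Figures are side artifacts — no
analysis result depends on them.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .neural import TrainingHistory
from .regression import EvalResult, ImportanceReport


def file_sha256(path: str | Path) -> str:
    """Hex digest of a file, for provenance logging."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def importance_frame(report: ImportanceReport, full: bool = True) -> pd.DataFrame:
    rows = report.full if full else report.ranked
    return pd.DataFrame(rows, columns=["feature", "importance"])


def plot_predicted_vs_actual(result: EvalResult, path: str | Path,
                             title: str = "") -> None:
    actual = [a for a, _ in result.pairs]
    pred = [p for _, p in result.pairs]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(actual, pred, s=18, alpha=0.7)
    lo, hi = min(actual + pred), max(actual + pred)
    ax.plot([lo, hi], [lo, hi], "k--", lw=1)
    ax.set_xlabel("actual")
    ax.set_ylabel("predicted")
    ax.set_title(title or f"R² = {result.r2:.2f}, MAE = {result.mae:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_sorted_predictions(result: EvalResult, path: str | Path,
                            title: str = "") -> None:
    """Predicted and actual values over test samples sorted by the actual target."""
    pairs = sorted(result.pairs)
    actual = [a for a, _ in pairs]
    pred = [p for _, p in pairs]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(actual, "k.-", label="actual", lw=1)
    ax.plot(pred, "o", color="tab:blue", ms=4, label="predicted")
    ax.set_xlabel("test sample (sorted by target)")
    ax.set_ylabel("target")
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_convergence(history: TrainingHistory, path: str | Path,
                     title: str = "") -> None:
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    epochs = range(1, len(history.train_loss) + 1)
    ax1.semilogy(epochs, history.train_loss, label="train")
    ax1.semilogy(epochs, history.val_loss, label="validation")
    ax1.set_xlabel("epoch")
    ax1.set_ylabel("MSE loss")
    ax1.legend()
    ax2.plot(epochs, history.train_r2, label="train")
    ax2.plot(epochs, history.val_r2, label="validation")
    ax2.set_xlabel("epoch")
    ax2.set_ylabel("R²")
    ax2.set_ylim(-0.5, 1.05)
    ax2.legend()
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
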