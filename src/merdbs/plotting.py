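"""Figures for training histories and ROC curves (Agg backend, file output)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .evaluate import RocCurve


def plot_history(history, path, title: str = "") -> None:
    """Train loss and per-head test accuracy against the training epoch."""
    fig, (ax_loss, ax_acc) = plt.subplots(1, 2, figsize=(9, 3.2), constrained_layout=True)
    ax_loss.plot(history["epoch"], history["train_loss"], color="tab:gray")
    ax_loss.set_xlabel("epoch")
    ax_loss.set_ylabel("train loss")
    ax_acc.plot(history["epoch"], history["acc_test_contra"], label="contralateral")
    if "acc_test_ipsi" in history and history["acc_test_ipsi"].notna().any():
        ax_acc.plot(history["epoch"], history["acc_test_ipsi"], label="ipsilateral")
    ax_acc.set_xlabel("epoch")
    ax_acc.set_ylabel("test accuracy")
    ax_acc.set_ylim(0, 1.02)
    ax_acc.legend(frameon=False)
    if title:
        fig.suptitle(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(curve: RocCurve, path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(3.6, 3.6), constrained_layout=True)
    ax.plot(curve.fpr, curve.tpr, drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], linestyle="--", color="tab:gray", linewidth=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(title or f"AUC = {curve.auc:.2f}")
    fig.savefig(path, dpi=120)
    plt.close(fig)
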