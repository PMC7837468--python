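"""Evaluation procedures: epoch selection, loss-ratio sweeps, ROC, stability
and the bilateral correlation report.

The reported accuracy of one training configuration is the *selected maximum
accuracy*: the best contralateral test accuracy among late epochs (after a
burn-in) whose training loss has essentially converged.  Sweeps rerun the
same data and seeds across loss-weight ratios so the ratio is the only thing
that changes.  Accuracy is counted per segment; a patient-level majority
vote is available separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .labeling import CLASSES, GOOD
from .model import ModelConfig, MultitaskOutcomeModel

logger = logging.getLogger(__name__)


def select_max_accuracy(
    history: pd.DataFrame, loss_epsilon: float = 0.05, min_epoch: int = 50
) -> tuple[float, int]:
    """Best late-epoch converged test accuracy and the epoch achieving it.

    Among epochs strictly after ``min_epoch`` whose train loss is below
    ``loss_epsilon``, returns the maximal contralateral test accuracy
    (earliest epoch on ties).  If no late epoch has converged, the loss
    condition is dropped with a logged warning.
    """
    if len(history) == 0:
        raise ValueError("empty training history")
    if history["epoch"].max() <= min_epoch:
        raise ValueError(
            f"history ends at epoch {history['epoch'].max()}, not beyond min_epoch={min_epoch}"
        )
    late = history[history["epoch"] > min_epoch]
    qualifying = late[late["train_loss"] < loss_epsilon]
    if qualifying.empty:
        logger.warning(
            "no epoch after %d reached train loss < %g; relaxing to all late epochs",
            min_epoch,
            loss_epsilon,
        )
        qualifying = late
    best = qualifying.loc[qualifying["acc_test_contra"].idxmax()]  # first max on ties
    return float(best["acc_test_contra"]), int(best["epoch"])


def stability(history: pd.DataFrame, window: int) -> float:
    """Population SD of contralateral test accuracy over the final ``window`` epochs."""
    if window < 2:
        raise ValueError("window must be at least 2")
    if window > len(history):
        raise ValueError(f"window {window} exceeds history length {len(history)}")
    tail = history["acc_test_contra"].to_numpy()[-window:]
    return float(np.std(tail, ddof=0))


@dataclass
class RocCurve:
    """ROC curve from a descending threshold sweep over unique scores."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_auc(scores: Sequence[float], labels: Sequence) -> RocCurve:
    """ROC curve and trapezoid AUC for probability-of-good scores.

    Equals the pairwise concordance probability with ties counted 1/2.
    ``labels`` may be class names or indices into ``CLASSES`` (positive class
    = good response).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "UOS":
        pos = labels == GOOD
    else:
        pos = labels == CLASSES.index(GOOD)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC curve")
    thresholds = np.unique(scores)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for thr in thresholds:
        called = scores >= thr
        tpr.append((called & pos).sum() / n_pos)
        fpr.append((called & ~pos).sum() / n_neg)
    tpr_arr, fpr_arr = np.asarray(tpr), np.asarray(fpr)
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    return RocCurve(thresholds=thresholds, tpr=tpr_arr, fpr=fpr_arr, auc=auc)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("at least 3 observations are required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlation_report(records) -> pd.DataFrame:
    """The five bilateral correlations computed on a cohort's clinical table.

    Pre-operative left/right scores, 6-month on- and off-stimulation
    left/right scores, the on/off ratio against the pre-operative score
    (contralateral side; expected null), and the left/right on/off ratios.
    """
    pre_l = np.array([r.updrs3_pre_left for r in records])
    pre_r = np.array([r.updrs3_pre_right for r in records])
    on_l = np.array([r.updrs3_on6m_left for r in records])
    on_r = np.array([r.updrs3_on6m_right for r in records])
    off_l = np.array([r.updrs3_off6m_left for r in records])
    off_r = np.array([r.updrs3_off6m_right for r in records])
    ratio_l = on_l / off_l
    ratio_r = on_r / off_r
    rows = []
    for name, x, y in [
        ("preop_left_vs_right", pre_l, pre_r),
        ("on6m_left_vs_right", on_l, on_r),
        ("off6m_left_vs_right", off_l, off_r),
        ("ratio_vs_preop_contra", ratio_r, pre_r),
        ("ratio_left_vs_right", ratio_l, ratio_r),
    ]:
        r, p = pearson_r(x, y)
        rows.append({"comparison": name, "r": r, "p": p, "n": len(x)})
    return pd.DataFrame(rows)


@dataclass
class SweepResult:
    """Selected max accuracy per loss-weight ratio (the ratio-sweep table)."""

    table: pd.DataFrame

    def best(self) -> pd.Series:
        return self.table.loc[self.table["max_accuracy"].idxmax()]


def loss_ratio_sweep(
    images,
    y_contra,
    y_ipsi,
    patient_ids,
    is_test,
    config: ModelConfig,
    ratios: Sequence[tuple[float, float]],
    loss_epsilon: float = 0.05,
    min_epoch: int = 50,
    segment_ids=None,
) -> SweepResult:
    """Train one model per contra:ipsi loss ratio with identical seeds.

    The data, split, weight initialisation and shuffling are shared across
    ratios, so the sweep isolates the loss-weight effect.
    """
    if len(ratios) == 0:
        raise ValueError("ratios must be non-empty")
    if len(set(tuple(r) for r in ratios)) != len(ratios):
        raise ValueError("duplicate loss ratios in sweep input")
    rows = []
    for w_c, w_i in ratios:
        cfg = replace(config, loss_weights=(float(w_c), float(w_i)))
        results = MultitaskOutcomeModel(
            images, y_contra, y_ipsi, patient_ids, is_test, cfg, segment_ids=segment_ids
        ).fit()
        acc, epoch = select_max_accuracy(results.history, loss_epsilon, min_epoch)
        rows.append(
            {
                "w_contra": float(w_c),
                "w_ipsi": float(w_i),
                "ratio": f"{w_c:g}:{w_i:g}",
                "max_accuracy": acc,
                "selected_epoch": epoch,
            }
        )
    return SweepResult(table=pd.DataFrame(rows))


def patient_majority_accuracy(scores, labels, patient_ids) -> float:
    """Patient-level accuracy by majority vote over a patient's segments.

    Reported as an extension alongside the segment-level accuracy.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    patient_ids = np.asarray(patient_ids)
    correct = []
    for pid in np.unique(patient_ids):
        m = patient_ids == pid
        vote = int(round(np.mean(scores[m] >= 0.5)))
        truth = int(np.unique(labels[m])[0])
        correct.append(vote == truth)
    return float(np.mean(correct))
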