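"""Outcome labels from bilateral UPDRS III scores and leakage-free patient splits.

Clinical benefit of STN DBS is summarised per body side as the ratio of the
6-month UPDRS part III motor score with stimulation on to the score with
stimulation off (off-medication).  A lower ratio means greater benefit.  The
ratio is dichotomised into a *good* / *moderate* response class with
side-specific cut-offs: the right body side (contralateral to the recorded
left hemisphere) improves more on average, so its cut-off is stricter.

Because the DBS lead contact spans 1.5 mm and recordings are taken every
0.5 mm, the three recording depths facing the active contact all inherit the
same clinical outcome: labels are attached per patient, not per segment.

Splits are assigned at the patient level so that no patient contributes
segments to both the training and the test partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: good-response cut-off on the on/off ratio, per body side.  A ratio strictly
#: below the cut-off is a good response; at or above it (including ratios > 1,
#: i.e. worsening under stimulation) the response is moderate.
THRESHOLDS = {"left": 0.70, "right": 0.60}

GOOD = "good"
MODERATE = "moderate"
#: class order used for integer coding throughout the package (good == 1).
CLASSES = (MODERATE, GOOD)

SIDES = ("left", "right")


class UndefinedRatioError(ValueError):
    """The on/off ratio is undefined (off-stimulation score is zero)."""


def onoff_ratio(on_score: float, off_score: float) -> float:
    """DBS on / DBS off UPDRS III ratio for one body side.

    Parameters
    ----------
    on_score, off_score
        6-month off-medication UPDRS part III side subtotals with
        stimulation on and off.  Scores must be non-negative and the
        off score strictly positive.
    """
    if not np.isfinite(on_score) or not np.isfinite(off_score):
        raise ValueError("UPDRS scores must be finite")
    if on_score < 0 or off_score < 0:
        raise ValueError("UPDRS scores must be non-negative")
    if off_score == 0:
        raise UndefinedRatioError("off-stimulation score of 0 leaves the ratio undefined")
    return float(on_score) / float(off_score)


def dichotomize(ratio: float, side: str) -> str:
    """Map an on/off ratio to the binary response class for ``side``.

    ``good`` is the half-open interval ``[0, 0.70)`` on the left and
    ``[0, 0.60)`` on the right; everything at or above the cut-off —
    including ratios above 1 — is ``moderate``.
    """
    if side not in THRESHOLDS:
        raise ValueError(f"unknown side {side!r}; expected one of {SIDES}")
    if not np.isfinite(ratio) or ratio < 0:
        raise ValueError(f"ratio must be finite and non-negative, got {ratio!r}")
    return GOOD if ratio < THRESHOLDS[side] else MODERATE


@dataclass(frozen=True)
class OutcomeLabel:
    """Per-side binary response class derived from the on/off ratio."""

    patient_id: str
    side: str
    ratio: float
    response: str = field(default="")

    def __post_init__(self) -> None:
        expected = dichotomize(self.ratio, self.side)
        if self.response == "":
            object.__setattr__(self, "response", expected)
        elif self.response != expected:
            raise ValueError(
                f"response {self.response!r} inconsistent with ratio {self.ratio} on {self.side}"
            )


@dataclass
class LabeledExample:
    """One MER segment joined with its patient's bilateral outcome labels.

    The recorded hemisphere is the left one, so the contralateral label is
    the right body side and the ipsilateral label the left body side.
    """

    segment_id: str
    patient_id: str
    depth_index: int
    label_contra: OutcomeLabel
    label_ipsi: OutcomeLabel
    split: str = "train"

    def __post_init__(self) -> None:
        if self.label_contra.patient_id != self.patient_id or self.label_ipsi.patient_id != self.patient_id:
            raise ValueError("labels must come from the example's own patient")
        if self.label_contra.side != "right" or self.label_ipsi.side != "left":
            raise ValueError("contralateral label must be the right side, ipsilateral the left")


def labels_for_record(record) -> tuple[OutcomeLabel, OutcomeLabel]:
    """(contralateral, ipsilateral) labels for one patient record.

    ``record`` needs ``patient_id`` and the four 6-month scores
    ``updrs3_{on,off}6m_{left,right}``; raises on missing/invalid scores.
    """
    ratio_right = onoff_ratio(record.updrs3_on6m_right, record.updrs3_off6m_right)
    ratio_left = onoff_ratio(record.updrs3_on6m_left, record.updrs3_off6m_left)
    contra = OutcomeLabel(record.patient_id, "right", ratio_right)
    ipsi = OutcomeLabel(record.patient_id, "left", ratio_left)
    return contra, ipsi


def attach_labels(
    segments: Sequence, records: Iterable
) -> tuple[list[LabeledExample], list[tuple[str, str]]]:
    """Join segments with their patient's bilateral labels.

    Returns ``(examples, exclusions)``: patients whose 6-month scores are
    missing or degenerate are excluded with a logged reason, mirroring the
    clinical exclusion of incomplete follow-ups, and contribute no examples.
    """
    by_patient = {r.patient_id: r for r in records}
    labels: dict[str, tuple[OutcomeLabel, OutcomeLabel]] = {}
    exclusions: list[tuple[str, str]] = []
    examples: list[LabeledExample] = []
    excluded: set[str] = set()
    for seg in segments:
        pid = seg.patient_id
        if pid in excluded:
            continue
        if pid not in labels:
            rec = by_patient.get(pid)
            if rec is None:
                exclusions.append((pid, "no patient record"))
                logger.warning("excluding patient %s: no patient record", pid)
                excluded.add(pid)
                continue
            try:
                labels[pid] = labels_for_record(rec)
            except (ValueError, TypeError) as exc:
                exclusions.append((pid, str(exc)))
                logger.warning("excluding patient %s: %s", pid, exc)
                excluded.add(pid)
                continue
        contra, ipsi = labels[pid]
        split = getattr(by_patient[pid], "split", "train")
        examples.append(
            LabeledExample(
                segment_id=getattr(seg, "segment_id", f"{pid}-{seg.depth_index}"),
                patient_id=pid,
                depth_index=seg.depth_index,
                label_contra=contra,
                label_ipsi=ipsi,
                split=split,
            )
        )
    return examples, exclusions


def _patient_class(item) -> str:
    """Response group of a patient-bearing object, by the contralateral label."""
    if hasattr(item, "label_contra"):
        return item.label_contra.response
    contra, _ = labels_for_record(item)
    return contra.response


def patient_level_split(
    items: Sequence,
    n_test_good: int = 2,
    n_test_moderate: int = 2,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Assign whole patients to train/test, stratified by response group.

    ``items`` may be :class:`LabeledExample` objects or patient records; the
    response group of a patient is defined by the contralateral (right-body)
    label, matching the test objective of distinguishing the contralateral
    outcome.  Exactly ``n_test_good`` good-response and ``n_test_moderate``
    moderate-response patients are drawn into the test set; everyone else
    trains.  Raises if either class cannot fill its quota or if the training
    set would lose a class entirely.
    """
    if rng is None:
        rng = np.random.default_rng()
    groups: dict[str, str] = {}
    for item in items:
        pid = item.patient_id
        if pid not in groups:
            groups[pid] = _patient_class(item)
    good = sorted(p for p, g in groups.items() if g == GOOD)
    moderate = sorted(p for p, g in groups.items() if g == MODERATE)
    if len(good) < n_test_good + 1 or len(moderate) < n_test_moderate + 1:
        raise ValueError(
            "not enough patients per response group for the requested test composition "
            f"(good={len(good)}, moderate={len(moderate)}, "
            f"requested test {n_test_good}+{n_test_moderate} with non-empty train classes)"
        )
    test_good = rng.choice(good, size=n_test_good, replace=False)
    test_moderate = rng.choice(moderate, size=n_test_moderate, replace=False)
    test = set(test_good) | set(test_moderate)
    return {pid: ("test" if pid in test else "train") for pid in groups}


def apply_split(examples: Sequence[LabeledExample], assignment: dict[str, str]) -> list[LabeledExample]:
    """Return copies of ``examples`` with splits taken from ``assignment``."""
    return [replace(ex, split=assignment[ex.patient_id]) for ex in examples]


# ---------------------------------------------------------------------------
# manifest round-trip

MANIFEST_COLUMNS = [
    "segment_id",
    "patient_id",
    "depth_index",
    "ratio_right",
    "ratio_left",
    "label_right",
    "label_left",
    "split",
]


def examples_to_frame(examples: Sequence[LabeledExample]) -> pd.DataFrame:
    rows = [
        {
            "segment_id": ex.segment_id,
            "patient_id": ex.patient_id,
            "depth_index": ex.depth_index,
            "ratio_right": ex.label_contra.ratio,
            "ratio_left": ex.label_ipsi.ratio,
            "label_right": ex.label_contra.response,
            "label_left": ex.label_ipsi.response,
            "split": ex.split,
        }
        for ex in examples
    ]
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def frame_to_examples(frame: pd.DataFrame) -> list[LabeledExample]:
    examples = []
    for row in frame.itertuples(index=False):
        examples.append(
            LabeledExample(
                segment_id=str(row.segment_id),
                patient_id=str(row.patient_id),
                depth_index=int(row.depth_index),
                label_contra=OutcomeLabel(str(row.patient_id), "right", float(row.ratio_right)),
                label_ipsi=OutcomeLabel(str(row.patient_id), "left", float(row.ratio_left)),
                split=str(row.split),
            )
        )
    return examples


def write_manifest(examples: Sequence[LabeledExample], path) -> None:
    examples_to_frame(examples).to_csv(path, index=False)


def read_manifest(path) -> list[LabeledExample]:
    return frame_to_examples(pd.read_csv(path))
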