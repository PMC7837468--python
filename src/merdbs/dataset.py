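"""Cohort -> classifier-ready scalogram image dataset.

Streams the synthetic cohort patient by patient, converts every segment to
its per-band scalogram images and keeps only the images plus labels, so the
raw waveforms (which dominate memory at 48 kHz x 4 s) never need to be held
all at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import labeling
from .cohort import BANDS, CohortConfig, PatientRecord, iter_cohort_segments
from .preprocess import PreprocessConfig, make_band_scalograms


@dataclass
class ScalogramDataset:
    """Labelled scalogram images for one cohort.

    ``images[band]`` is (N, H, W) float32 in [0, 1]; labels are integer
    indices into ``labeling.CLASSES`` (1 = good).  The contralateral label is
    the right body side, the ipsilateral label the left.
    """

    images: dict[str, np.ndarray]
    y_contra: np.ndarray
    y_ipsi: np.ndarray
    patient_ids: np.ndarray
    segment_ids: np.ndarray
    is_test: np.ndarray
    records: list[PatientRecord] = field(default_factory=list)

    @property
    def n_examples(self) -> int:
        return len(self.y_contra)

    def with_split(self, assignment: dict[str, str]) -> "ScalogramDataset":
        """Same dataset under a different patient-level split assignment."""
        is_test = np.array([assignment[p] == "test" for p in self.patient_ids])
        return ScalogramDataset(
            images=self.images,
            y_contra=self.y_contra,
            y_ipsi=self.y_ipsi,
            patient_ids=self.patient_ids,
            segment_ids=self.segment_ids,
            is_test=is_test,
            records=self.records,
        )


def build_dataset(
    cohort_config: CohortConfig,
    bands=BANDS,
    preprocess_config: PreprocessConfig | None = None,
) -> ScalogramDataset:
    """Simulate a cohort and preprocess every segment for every band."""
    if preprocess_config is None:
        preprocess_config = PreprocessConfig()
    images: dict[str, list[np.ndarray]] = {b: [] for b in bands}
    y_contra, y_ipsi, pids, sids, is_test = [], [], [], [], []
    records = []
    for rec, segments in iter_cohort_segments(cohort_config):
        records.append(rec)
        contra, ipsi = labeling.labels_for_record(rec)
        for seg in segments:
            for band in bands:
                images[band].append(make_band_scalograms(seg, band, preprocess_config).values)
            y_contra.append(labeling.CLASSES.index(contra.response))
            y_ipsi.append(labeling.CLASSES.index(ipsi.response))
            pids.append(rec.patient_id)
            sids.append(seg.segment_id)
            is_test.append(rec.split == "test")
    return ScalogramDataset(
        images={b: np.stack(v).astype(np.float32) for b, v in images.items()},
        y_contra=np.asarray(y_contra, dtype=int),
        y_ipsi=np.asarray(y_ipsi, dtype=int),
        patient_ids=np.asarray(pids),
        segment_ids=np.asarray(sids),
        is_test=np.asarray(is_test, dtype=bool),
        records=records,
    )


def resplit(dataset: ScalogramDataset, n_test_good: int, n_test_moderate: int, rng) -> ScalogramDataset:
    """Draw a fresh patient-level split for an existing dataset."""
    assignment = labeling.patient_level_split(
        dataset.records, n_test_good=n_test_good, n_test_moderate=n_test_moderate, rng=rng
    )
    return dataset.with_split(assignment)
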