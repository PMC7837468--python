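"""File formats for cohort artefacts: WAV waveforms, PNG scalograms, CSV tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image
from scipy.io import wavfile

from .cohort import MerSegment
from .preprocess import Scalogram


def write_segment_wav(segment: MerSegment, path) -> None:
    """Write a segment as a float32 WAV at its native sampling rate."""
    wavfile.write(str(path), int(segment.sampling_rate_hz), segment.samples.astype(np.float32))


def read_segment_wav(path, patient_id: str, depth_index: int = 0, segment_id: str = "") -> MerSegment:
    fs, samples = wavfile.read(str(path))
    return MerSegment(
        samples=np.asarray(samples, dtype=np.float32),
        sampling_rate_hz=int(fs),
        patient_id=patient_id,
        depth_index=depth_index,
        segment_id=segment_id or Path(path).stem,
    )


def write_scalogram_png(scalogram: Scalogram, path) -> None:
    """Write a [0, 1] scalogram image losslessly as 16-bit grayscale PNG."""
    values = np.clip(scalogram.values, 0.0, 1.0)
    img = (values * 65535.0).round().astype(np.uint16)
    Image.fromarray(img).save(str(path))

def read_scalogram_png(path, band: str = "", freqs_hz=None) -> Scalogram:
    img = np.asarray(Image.open(str(path)), dtype=np.float32) / 65535.0
    if freqs_hz is None:
        freqs_hz = np.arange(img.shape[0], 0, -1, dtype=float)
    return Scalogram(values=img, band=band, freqs_hz=np.asarray(freqs_hz), source=Path(path).stem)


def write_images_npz(path, images: dict[str, np.ndarray]) -> None:
    """Portable numeric container for per-band image stacks."""
    np.savez_compressed(str(path), **images)


def read_images_npz(path) -> dict[str, np.ndarray]:
    with np.load(str(path)) as data:
        return {k: data[k] for k in data.files}
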