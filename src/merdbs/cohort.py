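"""Synthetic MER cohort generator.

Stands in for the (undeposited) surgical cohort: per patient, a handful of
4-second extracellular microelectrode recordings from the left subthalamic
trajectory plus bilateral UPDRS part III scores before surgery and at
6 months with stimulation on and off.

The waveform model mixes the constituents practitioners describe in STN
recordings: 1/f broadband background, beta-band (13-30 Hz) oscillation,
a high-frequency oscillation (200-400 Hz), Poisson-bursting spike trains
convolved with a ~1.2 ms biphasic template, and a small unfiltered 60 Hz
mains component.  One configurable frequency band carries the
outcome-predictive signal: a per-patient latent responder feature scales the
amplitude of the component living in ``effect_band`` and simultaneously
drives the on/off outcome ratios of both body sides through asymmetric
couplings (contralateral stronger than ipsilateral), with shared and
independent noise calibrated so the left/right ratios reach a target
bilateral Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import labeling

logger = logging.getLogger(__name__)

BANDS = ("1-50", "50-500", "500-5000")


def parse_band(band: str) -> tuple[float, float]:
    """``"50-500"`` -> ``(50.0, 500.0)``."""
    try:
        low, high = (float(x) for x in str(band).split("-"))
    except ValueError as exc:
        raise ValueError(f"cannot parse band {band!r}; expected 'low-high' in Hz") from exc
    if not 0 < low < high:
        raise ValueError(f"band edges must satisfy 0 < low < high, got {band!r}")
    return low, high


class ConfigurationError(ValueError):
    """A cohort or pipeline configuration violates its invariants."""


# latent-model constants (see docs/methods.md): spread of the within-class
# responder feature, slope of the ratio on the latent, left/right correlation
# of the pre-op and 6-month-off score draws, and component base amplitudes.
LATENT_SD = 0.4
RATIO_SLOPE = 0.18
FEATURE_LOG_GAIN = 0.4
SEGMENT_FEATURE_JITTER = 0.1
PREOP_CORR = 0.77
OFF6M_CORR = 0.74
PREOP_MEAN = {"right": 12.41, "left": 12.76}
PREOP_SD = {"right": 5.19, "left": 5.39}
OFF6M_MEAN = {"right": 11.22, "left": 11.54}
OFF6M_SD = {"right": 4.35, "left": 4.39}
RATIO_CLIP = (0.0, 1.2)

BG_AMP = 1.0
BETA_AMP = 0.6
HFO_AMP = 0.5
SPIKE_AMP = 4.0
LINE_AMP = 0.05


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort.

    Defaults mirror the clinical cohort the generator emulates: 34 patients,
    696 segments in total (mean 20.47 per patient), 4-second recordings at
    48 kHz, predictive signal in the 50-500 Hz band, contralateral coupling
    stronger than ipsilateral, and a bilateral ratio correlation of 0.67.
    """

    seed: int
    n_patients: int = 34
    total_segments: Optional[int] = 696
    segments_per_patient: float = 20.47
    duration_s: float = 4.0
    sampling_rate_hz: int = 48_000
    effect_band: str = "50-500"
    effect_size: float = 1.5
    contra_coupling: float = 1.0
    ipsi_coupling: float = 0.3
    ratio_noise_sd: float = 0.08
    bilateral_corr_target: Optional[float] = 0.67
    n_test_good: int = 2
    n_test_moderate: int = 2
    line_noise: bool = True

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate_hz * self.duration_s))

    def validate(self) -> None:
        if self.sampling_rate_hz <= 0 or self.duration_s <= 0:
            raise ConfigurationError("sampling rate and duration must be positive")
        n = self.sampling_rate_hz * self.duration_s
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("sampling_rate_hz * duration_s must be an integer sample count")
        if self.n_patients < 4:
            raise ConfigurationError("n_patients must be at least 4")
        if not (self.contra_coupling >= self.ipsi_coupling >= 0):
            raise ConfigurationError("couplings must satisfy contra_coupling >= ipsi_coupling >= 0")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be non-negative")
        if self.ratio_noise_sd < 0:
            raise ConfigurationError("ratio_noise_sd must be non-negative")
        low, high = parse_band(self.effect_band)
        if high >= self.sampling_rate_hz / 2:
            raise ConfigurationError(
                f"effect band {self.effect_band} is not representable at "
                f"{self.sampling_rate_hz} Hz sampling"
            )
        if self.total_segments is not None and self.total_segments < 3 * self.n_patients:
            raise ConfigurationError("total_segments must allow at least one depth triplet per patient")


@dataclass
class MerSegment:
    """One single-channel extracellular recording segment.

    ``depth_index`` in {0, 1, 2} identifies the segment's position within the
    triplet of recording depths facing the active lead contact; all three
    depths of a patient share one clinical outcome.
    """

    samples: np.ndarray
    sampling_rate_hz: int
    patient_id: str
    side: str = "left"
    depth_index: int = 0
    segment_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("segment samples must be finite")
        if self.segment_id == "":
            self.segment_id = f"{self.patient_id}-d{self.depth_index}"

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate_hz


@dataclass
class PatientRecord:
    """Bilateral UPDRS part III scores for one patient.

    On-stimulation scores may exceed off-stimulation scores (worsening), so
    on/off ratios above 1 are possible and survive labeling as 'moderate'.
    """

    patient_id: str
    updrs3_pre_left: float
    updrs3_pre_right: float
    updrs3_off6m_left: float
    updrs3_off6m_right: float
    updrs3_on6m_left: float
    updrs3_on6m_right: float
    split: str = "train"

    def __post_init__(self) -> None:
        for name in (
            "updrs3_pre_left",
            "updrs3_pre_right",
            "updrs3_off6m_left",
            "updrs3_off6m_right",
            "updrs3_on6m_left",
            "updrs3_on6m_right",
        ):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    def ratio(self, side: str) -> float:
        if side == "left":
            return labeling.onoff_ratio(self.updrs3_on6m_left, self.updrs3_off6m_left)
        if side == "right":
            return labeling.onoff_ratio(self.updrs3_on6m_right, self.updrs3_off6m_right)
        raise ValueError(f"unknown side {side!r}")


# ---------------------------------------------------------------------------
# waveform synthesis


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-power noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz] / freqs[nz][0])
    spec *= shaping
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def spike_template(sampling_rate_hz: float, width_s: float = 1.2e-3) -> np.ndarray:
    """Biphasic exponential-decay spike kernel of ~1.2 ms.

    One sinusoidal cycle under an exponential decay; the ~0.6 ms lobes put
    the template's energy in the 500-5000 Hz band.
    """
    n = max(int(round(width_s * sampling_rate_hz)), 2)
    t = np.arange(n) / sampling_rate_hz
    kernel = np.sin(2 * np.pi * t / width_s) * np.exp(-t / (width_s / 4))
    peak = np.abs(kernel).max()
    return kernel / peak if peak > 0 else kernel


def simulate_mer_segment(
    band_feature_level: float,
    config: CohortConfig,
    rng: np.random.Generator,
    patient_id: str = "p000",
    depth_index: int = 0,
    segment_id: str = "",
) -> MerSegment:
    """Simulate one left-side MER segment.

    The component occupying ``config.effect_band`` has its amplitude scaled
    by ``band_feature_level`` (>= 0, 1 = baseline); the other components stay
    at baseline amplitude.  Deterministic given the generator state.
    """
    if band_feature_level < 0:
        raise ValueError("band_feature_level must be non-negative")
    config.validate()
    fs = config.sampling_rate_hz
    n = config.n_samples
    t = np.arange(n) / fs

    gain_low = band_feature_level if config.effect_band == "1-50" else 1.0
    gain_mid = band_feature_level if config.effect_band == "50-500" else 1.0
    gain_high = band_feature_level if config.effect_band == "500-5000" else 1.0

    x = BG_AMP * _pink_noise(n, rng)

    # beta oscillation with a slow amplitude envelope (1-50 Hz band)
    f_beta = rng.uniform(13.0, 30.0)
    env = 1.0 + 0.5 * np.sin(2 * np.pi * rng.uniform(0.1, 0.5) * t + rng.uniform(0, 2 * np.pi))
    x += BETA_AMP * gain_low * env * np.sin(2 * np.pi * f_beta * t + rng.uniform(0, 2 * np.pi))

    # high-frequency oscillation (50-500 Hz band)
    f_hfo = rng.uniform(200.0, 400.0)
    env = 1.0 + 0.5 * np.sin(2 * np.pi * rng.uniform(1.0, 4.0) * t + rng.uniform(0, 2 * np.pi))
    x += HFO_AMP * gain_mid * env * np.sin(2 * np.pi * f_hfo * t + rng.uniform(0, 2 * np.pi))

    # bursting spike train (500-5000 Hz band): Poisson burst onsets, short
    # bursts of spikes at ~6 ms intra-burst intervals, biphasic template
    impulses = np.zeros(n)
    n_bursts = rng.poisson(2.0 * config.duration_s)
    onsets = rng.uniform(0, config.duration_s, size=n_bursts)
    for onset in onsets:
        n_spk = 1 + rng.poisson(4.0)
        isis = 6e-3 + rng.exponential(2e-3, size=n_spk)
        times = onset + np.concatenate(([0.0], np.cumsum(isis[:-1])))
        idx = (times * fs).astype(int)
        idx = idx[idx < n]
        impulses[idx] -= rng.uniform(0.8, 1.2, size=len(idx))  # negative-going spikes
    x += SPIKE_AMP * gain_high * np.convolve(impulses, spike_template(fs), mode="same")

    if config.line_noise:
        x += LINE_AMP * np.sin(2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))

    return MerSegment(
        samples=x.astype(np.float32),
        sampling_rate_hz=fs,
        patient_id=patient_id,
        depth_index=depth_index,
        segment_id=segment_id,
    )


# ---------------------------------------------------------------------------
# latent outcome model


def latent_feature_variance(config: CohortConfig) -> float:
    """Variance of the latent responder feature u (two-class mixture)."""
    return (config.effect_size / 2.0) ** 2 + LATENT_SD**2


def noise_partition(config: CohortConfig) -> tuple[float, float]:
    """(shared_sd, extra_independent_sd) calibrating the bilateral correlation.

    The left/right ratios are ``ratio_s = mu_s - c_s u + eta + eps_s`` with
    ``c_s = RATIO_SLOPE * coupling_s``, shared noise eta and independent noise
    eps.  Because u is shared between sides the baseline correlation may
    exceed the target, in which case independent noise is added; if it falls
    short, shared noise is added.  Closed-form solution of
    ``r = (c_L c_R var_u + v) / sqrt((c_L^2 var_u + v + s^2)(c_R^2 var_u + v + s^2))``.
    """
    if config.bilateral_corr_target is None:
        return 0.0, 0.0
    r = float(config.bilateral_corr_target)
    if not 0.0 <= r < 1.0:
        raise ConfigurationError("bilateral_corr_target must lie in [0, 1)")
    var_u = latent_feature_variance(config)
    c_r = RATIO_SLOPE * config.contra_coupling
    c_l = RATIO_SLOPE * config.ipsi_coupling
    b = c_l * c_r * var_u
    a_r = c_r**2 * var_u + config.ratio_noise_sd**2
    a_l = c_l**2 * var_u + config.ratio_noise_sd**2
    r0 = b / np.sqrt(a_l * a_r) if a_l > 0 and a_r > 0 else 0.0
    if abs(r0 - r) < 1e-12:
        return 0.0, 0.0
    if r0 < r:
        # add shared noise v: (b + v)^2 = r^2 (a_l + v)(a_r + v)
        coeffs = [1.0 - r**2, 2 * b - r**2 * (a_l + a_r), b**2 - r**2 * a_l * a_r]
        roots = np.roots(coeffs)
        v = max(float(x) for x in roots if np.isreal(x) and x.real >= -1e-12)
        return float(np.sqrt(max(v, 0.0))), 0.0
    # too correlated already: add independent noise e per side
    # b^2 = r^2 (a_l + e)(a_r + e)
    coeffs = [r**2, r**2 * (a_l + a_r), r**2 * a_l * a_r - b**2]
    roots = np.roots(coeffs)
    e = max(float(x) for x in roots if np.isreal(x) and x.real >= -1e-12)
    return 0.0, float(np.sqrt(max(e, 0.0)))


@dataclass
class PatientLatents:
    patient_id: str
    responder_class: str  # generative class: 'good' or 'moderate'
    latent: float  # responder feature u
    feature_level: float  # amplitude multiplier for the effect-band component


def simulate_patient_records(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[list[PatientRecord], list[PatientLatents]]:
    """Draw the clinical table of a cohort (no waveforms).

    The generative responder class is balanced across the cohort; the
    dichotomised label may flip for borderline patients, as it would
    clinically.  Pre-op scores are drawn independently of the ratios so a
    pre-op-vs-ratio correlation check yields a null result.
    """
    shared_sd, extra_sd = noise_partition(config)
    indep_sd = float(np.hypot(config.ratio_noise_sd, extra_sd))
    records: list[PatientRecord] = []
    latents: list[PatientLatents] = []
    classes = np.array([labeling.GOOD, labeling.MODERATE] * ((config.n_patients + 1) // 2))[
        : config.n_patients
    ]
    rng.shuffle(classes)
    for i in range(config.n_patients):
        pid = f"p{i:03d}"
        sign = 1.0 if classes[i] == labeling.GOOD else -1.0
        u = sign * config.effect_size / 2.0 + rng.normal(0.0, LATENT_SD)
        eta = rng.normal(0.0, shared_sd) if shared_sd > 0 else 0.0
        ratio_r = np.clip(
            labeling.THRESHOLDS["right"] - RATIO_SLOPE * config.contra_coupling * u
            + eta + rng.normal(0.0, indep_sd),
            *RATIO_CLIP,
        )
        ratio_l = np.clip(
            labeling.THRESHOLDS["left"] - RATIO_SLOPE * config.ipsi_coupling * u
            + eta + rng.normal(0.0, indep_sd),
            *RATIO_CLIP,
        )
        # bilateral-correlated score draws (shared factor + side-specific factor)
        pre_shared, pre_l_own, pre_r_own = rng.standard_normal(3)
        lam = np.sqrt(PREOP_CORR)
        pre_right = float(np.clip(PREOP_MEAN["right"] + PREOP_SD["right"] * (lam * pre_shared + np.sqrt(1 - PREOP_CORR) * pre_r_own), 1.0, None))
        pre_left = float(np.clip(PREOP_MEAN["left"] + PREOP_SD["left"] * (lam * pre_shared + np.sqrt(1 - PREOP_CORR) * pre_l_own), 1.0, None))
        z_off = rng.standard_normal(3)
        lam = np.sqrt(OFF6M_CORR)
        off_right = float(np.clip(OFF6M_MEAN["right"] + OFF6M_SD["right"] * (lam * z_off[0] + np.sqrt(1 - OFF6M_CORR) * z_off[1]), 1.0, None))
        off_left = float(np.clip(OFF6M_MEAN["left"] + OFF6M_SD["left"] * (lam * z_off[0] + np.sqrt(1 - OFF6M_CORR) * z_off[2]), 1.0, None))
        records.append(
            PatientRecord(
                patient_id=pid,
                updrs3_pre_left=pre_left,
                updrs3_pre_right=pre_right,
                updrs3_off6m_left=off_left,
                updrs3_off6m_right=off_right,
                updrs3_on6m_left=float(ratio_l) * off_left,
                updrs3_on6m_right=float(ratio_r) * off_right,
            )
        )
        latents.append(
            PatientLatents(
                patient_id=pid,
                responder_class=str(classes[i]),
                latent=float(u),
                feature_level=float(np.exp(FEATURE_LOG_GAIN * u)),
            )
        )
    return records, latents


def _segment_counts(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-patient segment counts (>= 3 each)."""
    n = config.n_patients
    if config.total_segments is not None:
        base = config.total_segments // n
        rem = config.total_segments - base * n
        counts = np.full(n, base, dtype=int)
        extra = rng.choice(n, size=rem, replace=False)
        counts[extra] += 1
        return counts
    mean = max(config.segments_per_patient, 3.0)
    return 3 + rng.poisson(mean - 3.0, size=n)


def simulate_cohort(config: CohortConfig) -> tuple[list[MerSegment], list[PatientRecord]]:
    """Generate a full cohort: waveform segments plus clinical records.

    Deterministic given the config (including its seed).  Patient-level
    train/test splits are assigned with both response groups represented in
    the test set.
    """
    segments: list[MerSegment] = []
    records: list[PatientRecord] = []
    for rec, segs in iter_cohort_segments(config):
        records.append(rec)
        segments.extend(segs)
    return segments, records


def iter_cohort_segments(config: CohortConfig):
    """Yield ``(record, [segments of one patient])`` pairs without holding the
    whole cohort's waveforms in memory.  Same stream layout as
    :func:`simulate_cohort`, so the two agree bit-for-bit."""
    records, latents = simulate_patient_records(
        config, np.random.default_rng([config.seed, 0])
    )
    assignment = labeling.patient_level_split(
        records,
        n_test_good=config.n_test_good,
        n_test_moderate=config.n_test_moderate,
        rng=np.random.default_rng([config.seed, 1]),
    )
    for rec in records:
        rec.split = assignment[rec.patient_id]
    counts = _segment_counts(config, np.random.default_rng([config.seed, 2]))
    for i, (rec, lat) in enumerate(zip(records, latents)):
        rng = np.random.default_rng([config.seed, 3, i])
        segs = []
        for j in range(counts[i]):
            level = lat.feature_level * float(
                np.exp(rng.normal(0.0, SEGMENT_FEATURE_JITTER))
            )
            segs.append(
                simulate_mer_segment(
                    level,
                    config,
                    rng,
                    patient_id=rec.patient_id,
                    depth_index=j % 3,
                    segment_id=f"{rec.patient_id}-s{j:03d}",
                )
            )
        yield rec, segs


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "updrs3_pre_left": r.updrs3_pre_left,
                "updrs3_pre_right": r.updrs3_pre_right,
                "updrs3_off6m_left": r.updrs3_off6m_left,
                "updrs3_off6m_right": r.updrs3_off6m_right,
                "updrs3_on6m_left": r.updrs3_on6m_left,
                "updrs3_on6m_right": r.updrs3_on6m_right,
                "ratio_left": r.ratio("left"),
                "ratio_right": r.ratio("right"),
                "split": r.split,
            }
        )
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    return [
        PatientRecord(
            patient_id=str(row.patient_id),
            updrs3_pre_left=float(row.updrs3_pre_left),
            updrs3_pre_right=float(row.updrs3_pre_right),
            updrs3_off6m_left=float(row.updrs3_off6m_left),
            updrs3_off6m_right=float(row.updrs3_off6m_right),
            updrs3_on6m_left=float(row.updrs3_on6m_left),
            updrs3_on6m_right=float(row.updrs3_on6m_right),
            split=str(row.split),
        )
        for row in frame.itertuples(index=False)
    ]
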