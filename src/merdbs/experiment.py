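"""End-to-end experiment orchestration and the replicate battery.

``run_experiment`` executes simulate -> preprocess -> label -> train ->
evaluate from one :class:`ExperimentConfig` and writes every artefact under
an output root with enough metadata (config snapshot, seeds, version) to
reproduce the run.

``band_ratio_battery`` is the study design used for the headline synthetic
experiments: on one cohort, across replicate seeds, it trains the multitask
classifier per frequency band, the focus band at a balanced loss ratio, and
a single-task control, then tabulates selected max accuracies and late-epoch
stability.  ``desk_battery`` fixes the desk-scale study conditions
(40 patients, 12 kHz / 1 s segments, 64x64 images, tiny trunk, 60 epochs,
5 replicate seeds; see docs/methods.md for the scaling rationale).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, evaluate, io, labeling, plotting
from .cohort import BANDS, CohortConfig, iter_cohort_segments, records_to_frame
from .dataset import ScalogramDataset, build_dataset, resplit
from .model import ModelConfig, MultitaskOutcomeModel
from .preprocess import MorletParams, PreprocessConfig

logger = logging.getLogger(__name__)


def derive_seed(base_seed: int, *tags: int) -> int:
    """Deterministically derive a sub-seed (< 2^31) from a base seed."""
    ss = np.random.SeedSequence([int(base_seed), *map(int, tags)])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# replicate battery


def band_ratio_battery(
    dataset: ScalogramDataset,
    model_config: ModelConfig,
    bands=BANDS,
    focus_band: str = "50-500",
    focus_ratio: tuple[float, float] = (5.0, 1.0),
    baseline_ratio: tuple[float, float] = (1.0, 1.0),
    n_replicates: int = 5,
    base_seed: int = 0,
    n_test_good: int = 3,
    n_test_moderate: int = 3,
    loss_epsilon: float = 0.05,
    min_epoch: int = 50,
    stability_window: int = 10,
) -> pd.DataFrame:
    """Train the replicate grid and tabulate per-run metrics.

    Per replicate seed: one multitask run per band at ``focus_ratio``, one
    multitask run on ``focus_band`` at ``baseline_ratio``, and one
    single-task control on ``focus_band``.  Each replicate redraws the
    patient-level split and the network seeds; within a replicate all runs
    share seeds and split so band and loss ratio are the only differences.
    """
    rows = []
    for rep in range(n_replicates):
        seed = derive_seed(base_seed, 100, rep)
        split_rng = np.random.default_rng([seed, 7])
        ds = resplit(dataset, n_test_good, n_test_moderate, split_rng)
        runs = [(band, "multitask", focus_ratio) for band in bands]
        runs.append((focus_band, "multitask", baseline_ratio))
        runs.append((focus_band, "single_task", focus_ratio))
        for band, mode, ratio in runs:
            cfg = replace(model_config, seed=seed, mode=mode, loss_weights=tuple(ratio))
            t0 = time.perf_counter()
            results = MultitaskOutcomeModel.from_dataset(ds, band, cfg).fit()
            acc, epoch = evaluate.select_max_accuracy(results.history, loss_epsilon, min_epoch)
            rows.append(
                {
                    "replicate": rep,
                    "seed": seed,
                    "band": band,
                    "mode": mode,
                    "ratio": f"{ratio[0]:g}:{ratio[1]:g}",
                    "max_accuracy": acc,
                    "selected_epoch": epoch,
                    "stability": evaluate.stability(results.history, stability_window),
                    "final_accuracy": float(results.history["acc_test_contra"].iloc[-1]),
                    "wall_s": time.perf_counter() - t0,
                }
            )
            logger.info("battery run done: %s", rows[-1])
    return pd.DataFrame(rows)


def desk_cohort_config(seed: int, effect_size: float = 1.5, n_patients: int = 40) -> CohortConfig:
    """Desk-scale cohort: full latent structure, reduced rate and duration."""
    return CohortConfig(
        seed=seed,
        n_patients=n_patients,
        total_segments=n_patients * 20,
        duration_s=1.0,
        sampling_rate_hz=12_000,
        effect_band="50-500",
        effect_size=effect_size,
    )


def desk_model_config(seed: int = 0, **overrides) -> ModelConfig:
    """Tiny-trunk training configuration used by the desk-scale studies."""
    return ModelConfig.tiny(seed=seed, **overrides)


def desk_battery(base_seed: int, n_replicates: int = 5) -> pd.DataFrame:
    """The full desk-scale replicate battery from a single seed."""
    cohort = desk_cohort_config(seed=derive_seed(base_seed, 1))
    dataset = build_dataset(cohort)
    return band_ratio_battery(
        dataset,
        desk_model_config(),
        n_replicates=n_replicates,
        base_seed=base_seed,
    )


def null_accuracy(base_seed: int, n_replicates: int = 5) -> float:
    """Mean late-epoch test accuracy on an effect-free (null) cohort.

    The cohort carries no outcome-predictive signal, so the classifier
    should sit at chance; a small cohort and short training suffice.
    """
    cohort = CohortConfig(
        seed=derive_seed(base_seed, 2),
        n_patients=14,
        total_segments=14 * 12,
        duration_s=0.5,
        sampling_rate_hz=4_000,
        effect_band="50-500",
        effect_size=0.0,
    )
    pp = PreprocessConfig(image_size=(32, 32))
    dataset = build_dataset(cohort, bands=("50-500",), preprocess_config=pp)
    accs = []
    for rep in range(n_replicates):
        seed = derive_seed(base_seed, 3, rep)
        ds = resplit(dataset, 2, 2, np.random.default_rng([seed, 7]))
        cfg = ModelConfig(
            input_size=(32, 32),
            conv_blocks=((6,),),
            input_pool=1,
            epochs=30,
            seed=seed,
        )
        results = MultitaskOutcomeModel.from_dataset(ds, "50-500", cfg).fit()
        accs.append(float(results.history["acc_test_contra"].iloc[-10:].mean()))
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# config-file driven experiment


@dataclass
class ExperimentConfig:
    """One experiment = cohort + preprocessing + model + bands + ratio sweep."""

    seed: int
    cohort: CohortConfig
    model: ModelConfig
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    bands: tuple[str, ...] = BANDS
    ratios: tuple[tuple[float, float], ...] = ((5.0, 1.0), (1.0, 1.0))
    loss_epsilon: float = 0.05
    min_epoch: int = 50
    stability_window: int = 10
    save_waveforms: bool = False
    save_images: bool = False

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        if "seed" not in raw:
            raise ValueError("experiment config must declare a seed")
        seed = int(raw["seed"])
        cohort_kwargs = dict(raw.get("cohort", {}))
        cohort_kwargs.setdefault("seed", derive_seed(seed, 10))
        cohort = CohortConfig(**cohort_kwargs)
        pp_kwargs = dict(raw.get("preprocess", {}))
        if "image_size" in pp_kwargs:
            pp_kwargs["image_size"] = tuple(pp_kwargs["image_size"])
        morlet_kwargs = pp_kwargs.pop("morlet", {})
        preprocess = PreprocessConfig(morlet=MorletParams(**morlet_kwargs), **pp_kwargs)
        model_kwargs = dict(raw.get("model", {}))
        preset = model_kwargs.pop("preset", "tiny")
        for key in ("input_size", "head_widths"):
            if key in model_kwargs:
                model_kwargs[key] = tuple(model_kwargs[key])
        if "conv_blocks" in model_kwargs:
            model_kwargs["conv_blocks"] = tuple(tuple(b) for b in model_kwargs["conv_blocks"])
        if "loss_weights" in model_kwargs:
            model_kwargs["loss_weights"] = tuple(model_kwargs["loss_weights"])
        model_kwargs.setdefault("seed", derive_seed(seed, 11))
        factory = ModelConfig.vgg16 if preset == "vgg16" else ModelConfig.tiny
        model = factory(**model_kwargs)
        if model.input_size != preprocess.image_size:
            preprocess.image_size = model.input_size
        return cls(
            seed=seed,
            cohort=cohort,
            model=model,
            preprocess=preprocess,
            bands=tuple(raw.get("bands", BANDS)),
            ratios=tuple(tuple(r) for r in raw.get("ratios", [(5, 1), (1, 1)])),
            loss_epsilon=float(raw.get("loss_epsilon", 0.05)),
            min_epoch=int(raw.get("min_epoch", 50)),
            stability_window=int(raw.get("stability_window", 10)),
            save_waveforms=bool(raw.get("save_waveforms", False)),
            save_images=bool(raw.get("save_images", False)),
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "cohort": asdict(self.cohort),
            "preprocess": {
                **{k: v for k, v in asdict(self.preprocess).items() if k != "morlet"},
                "morlet": {
                    "omega0": self.preprocess.morlet.omega0,
                    "voices_per_octave": self.preprocess.morlet.voices_per_octave,
                },
            },
            "model": asdict(self.model),
            "bands": list(self.bands),
            "ratios": [list(r) for r in self.ratios],
            "loss_epsilon": self.loss_epsilon,
            "min_epoch": self.min_epoch,
            "stability_window": self.stability_window,
            "save_waveforms": self.save_waveforms,
            "save_images": self.save_images,
        }


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_experiment(config: ExperimentConfig, out_dir) -> Path:
    """Execute all stages and write the report directory.

    Stage failures abort with the stage name; artefacts written so far are
    left in place for debugging.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"version": __version__, "seed": config.seed, "stages": {}}
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - report the failing stage
                raise StageError(name, exc) from exc
            meta["stages"][name] = round(time.perf_counter() - t0, 3)
            logger.info("stage %s done in %.1fs", name, meta["stages"][name])
            return result

        return deco

    @stage("simulate+preprocess")
    def dataset() -> ScalogramDataset:
        ds = build_dataset(config.cohort, bands=config.bands, preprocess_config=config.preprocess)
        records_to_frame(ds.records).to_csv(out / "cohort.csv", index=False)
        if config.save_images:
            io.write_images_npz(out / "images.npz", ds.images)
        if config.save_waveforms:
            wav_dir = out / "waveforms"
            wav_dir.mkdir(exist_ok=True)
            for _, segments in iter_cohort_segments(config.cohort):
                for seg in segments:
                    io.write_segment_wav(seg, wav_dir / f"{seg.segment_id}.wav")
        return ds

    @stage("label")
    def manifest() -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "segment_id": dataset.segment_ids,
                "patient_id": dataset.patient_ids,
                "label_right": [labeling.CLASSES[i] for i in dataset.y_contra],
                "label_left": [labeling.CLASSES[i] for i in dataset.y_ipsi],
                "split": np.where(dataset.is_test, "test", "train"),
            }
        )
        frame.to_csv(out / "manifest.csv", index=False)
        return frame

    @stage("train")
    def runs() -> pd.DataFrame:
        rows = []
        for band in config.bands:
            for ratio in config.ratios:
                cfg = replace(config.model, loss_weights=tuple(ratio))
                results = MultitaskOutcomeModel.from_dataset(dataset, band, cfg).fit()
                acc, epoch = evaluate.select_max_accuracy(
                    results.history, config.loss_epsilon, config.min_epoch
                )
                tag = f"band{band}_ratio{ratio[0]:g}-{ratio[1]:g}"
                results.save_history(out / f"history_{tag}.csv")
                plotting.plot_history(results.history, out / f"history_{tag}.png", title=tag)
                scores, labels = results.test_scores()
                if len(np.unique(labels)) == 2:
                    curve = evaluate.roc_auc(scores, labels)
                    plotting.plot_roc(curve, out / f"roc_{tag}.png", title=tag)
                    auc = curve.auc
                else:
                    auc = np.nan
                rows.append(
                    {
                        "band": band,
                        "ratio": f"{ratio[0]:g}:{ratio[1]:g}",
                        "max_accuracy": acc,
                        "selected_epoch": epoch,
                        "stability": evaluate.stability(
                            results.history, min(config.stability_window, len(results.history))
                        ),
                        "auc": auc,
                    }
                )
        table = pd.DataFrame(rows)
        table.to_csv(out / "runs.csv", index=False)
        return table

    @stage("evaluate")
    def report() -> None:
        correlations = evaluate.correlation_report(dataset.records)
        correlations.to_csv(out / "correlations.csv", index=False)
        lines = [
            "# Experiment report",
            "",
            f"- package version: {__version__}",
            f"- seed: {config.seed}",
            f"- cohort: {config.cohort.n_patients} patients, {dataset.n_examples} segments",
            f"- bands: {', '.join(config.bands)}",
            "",
            "## Training runs",
            "",
            runs.to_markdown(index=False),
            "",
            "## Bilateral correlations",
            "",
            correlations.to_markdown(index=False),
            "",
        ]
        (out / "report.md").write_text("\n".join(lines))

    with open(out / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return out
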