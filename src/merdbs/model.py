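"""Shared-trunk multitask classifier for bilateral DBS outcome prediction.

A VGG-style convolutional trunk is shared between two task-specific fully
connected heads (widths 120, 120, 16, 2 with dropout 0.2 after each hidden
layer): one head predicts the contralateral (right-body) response class,
the other the ipsilateral (left-body) class.  Training minimises the
weighted joint loss

    L = w_contra * CE(contra head) + w_ipsi * CE(ipsi head)

with plain mini-batch gradient descent.  Only the weight *ratio* is
semantically meaningful; the loss value itself is not normalised (scaling
both weights by c scales L by exactly c), but the training step divides the
gradient by the weight sum so that the effective step size depends only on
the ratio.  In single-task mode only the contralateral head exists and L
reduces to its cross-entropy.

The user-facing objects follow the model/results idiom:
:class:`MultitaskOutcomeModel` is built from a labelled image dataset and
``fit()`` returns a :class:`MultitaskOutcomeResults` carrying the per-epoch
history, the trained network, predictions and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn
from .cohort import ConfigurationError
from .labeling import CLASSES

logger = logging.getLogger(__name__)

# tags deriving independent per-purpose rng streams from the one seed
_INIT, _DROPOUT, _SHUFFLE = 11, 12, 13


class LeakageError(RuntimeError):
    """A patient contributes examples to both train and test."""


@dataclass
class ModelConfig:
    """Architecture and optimisation settings.

    ``conv_blocks`` lists the convolution channel widths per block; every
    block is followed by 2x2 max pooling.  ``input_pool`` optionally average-
    pools the input image by 2 that many times before the trunk (a cheap
    image downsampling used by the desk-scale configuration).  ``head_widths``
    ends in the two response classes.  The full-size configuration
    (:meth:`vgg16`) carries the 13-conv-layer VGG16 trunk at 224x224 input
    with learning rate 0.001; the desk-scale :meth:`tiny` configuration keeps
    the head/dropout/optimiser structure but shrinks the trunk so a full
    training sweep runs on one CPU.
    """

    input_size: tuple[int, int] = (64, 64)
    conv_blocks: tuple[tuple[int, ...], ...] = ((6,), (12,))
    input_pool: int = 1
    head_widths: tuple[int, ...] = (120, 120, 16, 2)
    dropout_rate: float = 0.2
    learning_rate: float = 0.05
    loss_weights: tuple[float, float] = (1.0, 1.0)
    epochs: int = 60
    batch_size: int = 32
    seed: int = 0
    mode: str = "multitask"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.head_widths[-1] != 2:
            raise ConfigurationError("head must end in the two response classes")
        w_c, w_i = self.loss_weights
        if w_c < 0 or w_i < 0:
            raise ConfigurationError("loss weights must be non-negative")
        if w_c + w_i == 0:
            raise ConfigurationError("loss weights must not both be zero")
        if self.mode not in ("multitask", "single_task"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning rate must be positive")
        n_halvings = self.input_pool + len(self.conv_blocks)
        h, w = self.input_size
        if h % 2**n_halvings or w % 2**n_halvings:
            raise ConfigurationError(
                f"input {self.input_size} is not divisible by the trunk's total "
                f"downsampling factor 2^{n_halvings}"
            )

    @property
    def n_heads(self) -> int:
        return 1 if self.mode == "single_task" else 2

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """Desk-scale configuration: 64x64 input, two small conv blocks."""
        return cls(**overrides)

    @classmethod
    def vgg16(cls, **overrides) -> "ModelConfig":
        """Full-size configuration mirroring the VGG16 trunk."""
        defaults = dict(
            input_size=(224, 224),
            conv_blocks=((64, 64), (128, 128), (256, 256, 256), (512, 512, 512), (512, 512, 512)),
            input_pool=0,
            learning_rate=0.001,
            epochs=100,
        )
        defaults.update(overrides)
        return cls(**defaults)


class MultitaskNetwork:
    """Shared trunk + one or two task-specific heads (see :func:`build_model`)."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        seed = config.seed
        self.trunk: list[nn.Layer] = []
        for _ in range(config.input_pool):
            self.trunk.append(nn.AvgPool2())
        c_in, (h, w) = 1, config.input_size
        h, w = h // 2**config.input_pool, w // 2**config.input_pool
        layer_idx = 0
        for block in config.conv_blocks:
            for c_out in block:
                self.trunk.append(nn.Conv2d(c_in, c_out, np.random.default_rng([seed, _INIT, layer_idx])))
                self.trunk.append(nn.ReLU())
                c_in = c_out
                layer_idx += 1
            self.trunk.append(nn.MaxPool2())
            h, w = h // 2, w // 2
        if h < 1 or w < 1:
            raise ConfigurationError("input smaller than the trunk's total downsampling")
        for layer in self.trunk:
            if isinstance(layer, nn.Conv2d):
                layer.input_grad = False  # nothing upstream consumes it
                break
        self.trunk.append(nn.Flatten())
        flat = c_in * h * w
        self.heads: list[list[nn.Layer]] = []
        for head_idx in range(config.n_heads):
            layers: list[nn.Layer] = []
            n_in = flat
            base = 1000 * (head_idx + 1)
            for j, width in enumerate(config.head_widths):
                layers.append(nn.Dense(n_in, width, np.random.default_rng([seed, _INIT, base + j])))
                if j < len(config.head_widths) - 1:
                    layers.append(nn.ReLU())
                    layers.append(
                        nn.Dropout(config.dropout_rate, np.random.default_rng([seed, _DROPOUT, base + j]))
                    )
                n_in = width
            self.heads.append(layers)

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> list[np.ndarray]:
        """Logits per head for a batch of (N, 1, H, W) images."""
        features = nn.run_forward(self.trunk, x.astype(nn.DTYPE, copy=False), train=train)
        return [nn.run_forward(head, features, train=train) for head in self.heads]

    def backward(self, dlogits: Sequence[np.ndarray]) -> None:
        dfeat = None
        for head, dy in zip(self.heads, dlogits):
            d = nn.run_backward(head, dy)
            dfeat = d if dfeat is None else dfeat + d
        nn.run_backward(self.trunk, dfeat)

    def sgd_step(self, lr: float) -> None:
        nn.sgd_step(self.trunk, lr)
        for head in self.heads:
            nn.sgd_step(head, lr)

    # -- bookkeeping -------------------------------------------------------
    @property
    def all_layers(self) -> list[nn.Layer]:
        return self.trunk + [layer for head in self.heads for layer in head]

    @property
    def n_params(self) -> int:
        return nn.count_params(self.all_layers)

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.all_layers:
            if layer.trainable:
                out.extend([layer.weight.copy(), layer.bias.copy()])
        return out

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.all_layers:
            if layer.trainable:
                layer.weight = np.asarray(next(it), dtype=nn.DTYPE)
                layer.bias = np.asarray(next(it), dtype=nn.DTYPE)

    def save(self, path) -> None:
        np.savez(path, *self.get_weights())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.set_weights([data[k] for k in data.files])


def build_model(config: ModelConfig) -> MultitaskNetwork:
    """Construct the (untrained) network for ``config``."""
    return MultitaskNetwork(config)


def multitask_loss(logits_contra, logits_ipsi, labels_contra, labels_ipsi, w_contra, w_ipsi) -> float:
    """Weighted joint softmax cross-entropy (mean over the batch)."""
    loss, _, _ = multitask_loss_grads(
        logits_contra, logits_ipsi, labels_contra, labels_ipsi, w_contra, w_ipsi
    )
    return loss


def multitask_loss_grads(logits_contra, logits_ipsi, labels_contra, labels_ipsi, w_contra, w_ipsi):
    """Joint loss and its gradients w.r.t. both heads' logits."""
    if w_contra < 0 or w_ipsi < 0:
        raise ValueError("loss weights must be non-negative")
    if w_contra + w_ipsi == 0:
        raise ValueError("loss weights must not both be zero")
    loss_c, grad_c = nn.softmax_cross_entropy(logits_contra, labels_contra)
    loss_i, grad_i = nn.softmax_cross_entropy(logits_ipsi, labels_ipsi)
    loss = w_contra * loss_c + w_ipsi * loss_i
    return float(loss), w_contra * grad_c, w_ipsi * grad_i


def _accuracy(logits: np.ndarray, labels: np.ndarray) -> float:
    return float((logits.argmax(axis=1) == labels).mean())


class MultitaskOutcomeModel:
    """Outcome classifier built from a labelled scalogram-image dataset.

    Parameters
    ----------
    images : (N, H, W) float array of band scalogram images in [0, 1]
    y_contra, y_ipsi : (N,) int arrays, class indices into
        ``labeling.CLASSES`` (1 = good response)
    patient_ids : (N,) array of patient identifiers (leakage check)
    is_test : (N,) boolean array marking the held-out patients' segments
    config : ModelConfig
    """

    def __init__(self, images, y_contra, y_ipsi, patient_ids, is_test, config: ModelConfig,
                 segment_ids=None):
        images = np.asarray(images, dtype=nn.DTYPE)
        if images.ndim != 3:
            raise ValueError("images must be (N, H, W)")
        if images.shape[1:] != tuple(config.input_size):
            raise ConfigurationError(
                f"images of shape {images.shape[1:]} do not match config.input_size {config.input_size}"
            )
        self.images = images[:, None, :, :]  # single channel
        self.y_contra = np.asarray(y_contra, dtype=int)
        self.y_ipsi = np.asarray(y_ipsi, dtype=int)
        self.patient_ids = np.asarray(patient_ids)
        self.is_test = np.asarray(is_test, dtype=bool)
        self.config = config
        if segment_ids is not None:
            # canonical example order: training is then invariant to the
            # order the manifest happened to arrive in
            order = np.argsort(np.asarray(segment_ids))
            self.images = self.images[order]
            self.y_contra = self.y_contra[order]
            self.y_ipsi = self.y_ipsi[order]
            self.patient_ids = self.patient_ids[order]
            self.is_test = self.is_test[order]
        n = len(self.images)
        for arr in (self.y_contra, self.y_ipsi, self.patient_ids, self.is_test):
            if len(arr) != n:
                raise ValueError("all per-example arrays must share a length")
        if not self.is_test.any() or self.is_test.all():
            raise ValueError("both a train and a test split are required")

    @classmethod
    def from_dataset(cls, dataset, band: str, config: ModelConfig) -> "MultitaskOutcomeModel":
        """Build from a :class:`merdbs.dataset.ScalogramDataset` for one band."""
        return cls(
            images=dataset.images[band],
            y_contra=dataset.y_contra,
            y_ipsi=dataset.y_ipsi,
            patient_ids=dataset.patient_ids,
            is_test=dataset.is_test,
            config=config,
            segment_ids=dataset.segment_ids,
        )

    def _assert_no_leakage(self) -> None:
        train_p = set(self.patient_ids[~self.is_test])
        test_p = set(self.patient_ids[self.is_test])
        overlap = train_p & test_p
        if overlap:
            raise LeakageError(f"patients in both splits: {sorted(overlap)}")

    def fit(self, verbose: bool = False) -> "MultitaskOutcomeResults":
        """Train with mini-batch gradient descent and record the history."""
        self._assert_no_leakage()
        cfg = self.config
        network = build_model(cfg)
        x_train = self.images[~self.is_test] - 0.5  # centre the [0, 1] images
        x_test = self.images[self.is_test] - 0.5
        yc_tr, yi_tr = self.y_contra[~self.is_test], self.y_ipsi[~self.is_test]
        yc_te, yi_te = self.y_contra[self.is_test], self.y_ipsi[self.is_test]
        w_c, w_i = cfg.loss_weights
        single = cfg.mode == "single_task"
        shuffle_rng = np.random.default_rng([cfg.seed, _SHUFFLE])
        n = len(x_train)
        rows = []
        for epoch in range(1, cfg.epochs + 1):
            order = shuffle_rng.permutation(n)
            losses = []
            correct_c = correct_i = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb = x_train[idx]
                logits = network.forward(xb, train=True)
                if single:
                    loss, grad = nn.softmax_cross_entropy(logits[0], yc_tr[idx])
                    grads = [grad]
                else:
                    # gradients use sum-normalised weights so the effective
                    # step size depends only on the weight *ratio*; the
                    # recorded loss keeps the raw weighting
                    total = w_c + w_i
                    norm_loss, gc, gi = multitask_loss_grads(
                        logits[0], logits[1], yc_tr[idx], yi_tr[idx], w_c / total, w_i / total
                    )
                    loss = norm_loss * total
                    grads = [gc, gi]
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}; try a smaller learning rate"
                    )
                network.backward(grads)
                network.sgd_step(cfg.learning_rate)
                losses.append(loss)
                correct_c += int((logits[0].argmax(axis=1) == yc_tr[idx]).sum())
                if not single:
                    correct_i += int((logits[1].argmax(axis=1) == yi_tr[idx]).sum())
            test_logits = network.forward(x_test, train=False)
            row = {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "acc_train_contra": correct_c / n,
                "acc_train_ipsi": (correct_i / n) if not single else np.nan,
                "acc_test_contra": _accuracy(test_logits[0], yc_te),
                "acc_test_ipsi": _accuracy(test_logits[1], yi_te) if not single else np.nan,
            }
            rows.append(row)
            if verbose:
                logger.info(
                    "epoch %d loss %.4f test acc (contra) %.3f",
                    epoch,
                    row["train_loss"],
                    row["acc_test_contra"],
                )
        history = pd.DataFrame(rows)
        return MultitaskOutcomeResults(model=self, network=network, history=history)


@dataclass
class MultitaskOutcomeResults:
    """Fit artefacts: trained network, per-epoch history, prediction helpers."""

    model: MultitaskOutcomeModel
    network: MultitaskNetwork
    history: pd.DataFrame

    def predict_proba(self, images: np.ndarray) -> list[np.ndarray]:
        """Per-head class probabilities (columns ordered as ``CLASSES``)."""
        images = np.asarray(images, dtype=nn.DTYPE)
        if images.ndim == 3:
            images = images[:, None, :, :]
        logits = self.network.forward(images - 0.5, train=False)
        return [nn.softmax(l) for l in logits]

    def test_scores(self, head: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """(probability of good, true labels) on the held-out segments."""
        x = self.model.images[self.model.is_test, 0]
        proba = self.predict_proba(x)[head]
        good_col = CLASSES.index("good")
        y = self.model.y_contra if head == 0 else self.model.y_ipsi
        return proba[:, good_col], y[self.model.is_test]

    def summary(self) -> str:
        cfg = self.model.config
        last = self.history.iloc[-1]
        best = self.history["acc_test_contra"].max()
        lines = [
            "Multitask outcome classifier" if cfg.mode == "multitask" else "Single-task outcome classifier",
            "=" * 46,
            f"parameters:            {self.network.n_params:,}",
            f"input size:            {cfg.input_size[0]}x{cfg.input_size[1]}",
            f"loss weights (R:L):    {cfg.loss_weights[0]:g}:{cfg.loss_weights[1]:g}",
            f"learning rate:         {cfg.learning_rate:g}",
            f"epochs:                {cfg.epochs}",
            f"train segments:        {int((~self.model.is_test).sum())}",
            f"test segments:         {int(self.model.is_test.sum())}",
            f"final train loss:      {last['train_loss']:.4f}",
            f"final test accuracy:   {last['acc_test_contra']:.4f} (contralateral)",
            f"best test accuracy:    {best:.4f} (contralateral)",
        ]
        return "\n".join(lines)

    def save_history(self, path) -> None:
        self.history.to_csv(path, index=False)
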