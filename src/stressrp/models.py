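"""Stress classifiers: multimodal Cont-RP CNN and its neural baselines.

Four architectures share one blueprint (:class:`ModelSpec`):

* ``multimodal-cnn`` — three VGG-style branches, one per channel's
  recurrence-plot image, each with five convolution blocks (2, 2, 3, 3, 3
  conv layers; 3x3 kernels, stride 1; ReLU; 2x2 stride-2 max pooling) and
  global average pooling to a 256-dim vector; the three vectors are
  concatenated to a 768-dim fused representation feeding a dense head that
  outputs stressed/relaxed probabilities.
* ``unimodal-cnn:<channel>`` — a single branch plus head.
* ``multimodal-1d-cnn`` — the same block layout with 1-D convolutions over
  the raw preprocessed sequences instead of recurrence images.
* ``frozen-vgg`` — the 2-D multimodal layout with branch convolutions
  frozen at initialization; only the fusion head trains.

Training is plain SGD on two-class cross-entropy, seeded end to end.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from stressrp import nn
from stressrp.nn import DTYPE

__all__ = [
    "CLASSES",
    "ModelSpec",
    "TrainConfig",
    "TrainedModel",
    "ModelHandle",
    "build_branch_cnn",
    "build_multimodal_cnn",
    "build_unimodal_cnn",
    "build_multimodal_1d_cnn",
    "build_frozen_vgg_baseline",
    "train_model",
    "predict_proba",
]

#: Class order of every probability output; index 1 ("stressed") is the
#: positive class throughout the package.
CLASSES = ("relaxed", "stressed")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture constants shared by every classifier variant."""

    branch_channels: tuple[int, ...] = (16, 32, 64, 128, 256)
    conv_layers_per_block: tuple[int, ...] = (2, 2, 3, 3, 3)
    kernel_size: int = 3
    pool_size: int = 2
    input_size: int = 64
    head_hidden_dim: int = 128

    def __post_init__(self) -> None:
        if len(self.branch_channels) != len(self.conv_layers_per_block):
            raise ValueError("branch_channels and conv_layers_per_block "
                             "must have the same number of blocks")
        if any(c < 1 for c in self.branch_channels):
            raise ValueError("channel counts must be >= 1")
        if any(c < 1 for c in self.conv_layers_per_block):
            raise ValueError("conv layer counts must be >= 1")

    @property
    def n_blocks(self) -> int:
        return len(self.branch_channels)

    @property
    def branch_output_dim(self) -> int:
        return self.branch_channels[-1]

    @property
    def fused_dim(self) -> int:
        return 3 * self.branch_output_dim

    def validate_input_size(self) -> None:
        if self.input_size % (self.pool_size ** self.n_blocks) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by "
                f"{self.pool_size ** self.n_blocks} "
                f"({self.n_blocks} pooling halvings)")


@dataclass(frozen=True)
class TrainConfig:
    """SGD hyperparameters; defaults are the chosen operating point."""

    learning_rate: float = 0.001
    batch_size: int = 4
    epochs: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("learning_rate > 0, batch_size >= 1, "
                             "epochs >= 0 required")


def _branch_layers(spec: ModelSpec, rng: np.random.Generator,
                   one_dim: bool) -> list[nn.Layer]:
    conv = nn.Conv1d if one_dim else nn.Conv2d
    pool = nn.MaxPool1d if one_dim else nn.MaxPool2d
    gap = nn.GlobalAvgPool1d if one_dim else nn.GlobalAvgPool2d
    layers: list[nn.Layer] = []
    cin = 1
    for cout, n_convs in zip(spec.branch_channels,
                             spec.conv_layers_per_block):
        for _ in range(n_convs):
            layers.append(conv(cin, cout, spec.kernel_size, rng))
            layers.append(nn.ReLU())
            cin = cout
        layers.append(pool())
    layers.append(gap())
    return layers


class ModelHandle:
    """Buildable/trainable network: branch stacks plus fusion head.

    ``forward`` takes ``(N, n_branches, H, W)`` image stacks for 2-D
    variants or ``(N, n_branches, L)`` sequence stacks for the 1-D variant;
    each branch consumes its own channel.
    """

    def __init__(self, tag: str, spec: ModelSpec, n_branches: int,
                 one_dim: bool, seed: int, freeze_branches: bool = False):
        if not one_dim:
            spec.validate_input_size()
        self.tag = tag
        self.spec = spec
        self.n_branches = n_branches
        self.one_dim = one_dim
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.branches = [nn.Sequential(_branch_layers(spec, rng, one_dim),
                                       frozen=freeze_branches)
                         for _ in range(n_branches)]
        fused = n_branches * spec.branch_output_dim
        self.head = nn.Sequential([
            nn.Dense(fused, spec.head_hidden_dim, rng),
            nn.ReLU(),
            nn.Dense(spec.head_hidden_dim, len(CLASSES), rng),
        ])

    # -- forward / backward over the fused architecture ------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        expected_ndim = 3 if self.one_dim else 4
        if x.ndim != expected_ndim or x.shape[1] != self.n_branches:
            raise ValueError(
                f"{self.tag}: expected (N, {self.n_branches}, ...) with "
                f"{expected_ndim} axes, got shape {x.shape}")
        if self.one_dim:
            min_len = self.spec.pool_size ** self.spec.n_blocks
            if x.shape[2] < min_len:
                raise ValueError(
                    f"{self.tag}: sequence length {x.shape[2]} shorter than "
                    f"{min_len} (needs {self.spec.n_blocks} pooling halvings)")
        elif x.shape[2] != self.spec.input_size or x.shape[3] != self.spec.input_size:
            raise ValueError(
                f"{self.tag}: expected {self.spec.input_size}x"
                f"{self.spec.input_size} images, got {x.shape[2:]}")
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = self._check_input(x)
        outs = [branch.forward(x[:, i:i + 1])
                for i, branch in enumerate(self.branches)]
        self._fused = np.concatenate(outs, axis=1)
        return self.head.forward(self._fused)

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.head.backward(dlogits)
        d = self.spec.branch_output_dim
        for i, branch in enumerate(self.branches):
            if not branch.frozen:
                branch.backward(dfused[:, i * d:(i + 1) * d])

    def modules(self):
        return [*self.branches, self.head]

    def predict_proba(self, x: np.ndarray,
                      batch_size: int = 32) -> np.ndarray:
        x = self._check_input(x)
        chunks = [nn.softmax(self.forward(x[i:i + batch_size]))
                  for i in range(0, len(x), batch_size)]
        return np.concatenate(chunks, axis=0).astype(float)

    def state(self) -> list[np.ndarray]:
        out = []
        for module in self.modules():
            out.extend(module.state())
        return out

    def branch_state(self) -> list[np.ndarray]:
        out = []
        for branch in self.branches:
            out.extend(branch.state())
        return out


def build_branch_cnn(spec: ModelSpec, seed: int = 0) -> nn.Sequential:
    """One 2-D convolutional branch: RP image -> branch_output_dim vector."""
    spec.validate_input_size()
    rng = np.random.default_rng(seed)
    return nn.Sequential(_branch_layers(spec, rng, one_dim=False))


def build_multimodal_cnn(spec: ModelSpec, seed: int = 0) -> ModelHandle:
    """Three-branch Cont-RP CNN with a fused 3x256 = 768 representation."""
    return ModelHandle("multimodal-cnn", spec, n_branches=3, one_dim=False,
                       seed=seed)


def build_unimodal_cnn(spec: ModelSpec, channel: str,
                       seed: int = 0) -> ModelHandle:
    """Single-channel Cont-RP CNN baseline."""
    return ModelHandle(f"unimodal-cnn:{channel}", spec, n_branches=1,
                       one_dim=False, seed=seed)


def build_multimodal_1d_cnn(spec: ModelSpec, seed: int = 0) -> ModelHandle:
    """Three-branch 1-D CNN over raw preprocessed sequences."""
    return ModelHandle("multimodal-1d-cnn", spec, n_branches=3, one_dim=True,
                       seed=seed)


def build_frozen_vgg_baseline(spec: ModelSpec,
                              weights_mode: str = "random",
                              seed: int = 0) -> ModelHandle:
    """Multimodal CNN with frozen branch convolutions; only the head trains.

    ``weights_mode="random"`` freezes the seeded random initialization (no
    external weights needed); ``"pretrained"`` would require a weight file
    and is rejected explicitly since none is bundled.
    """
    if weights_mode == "pretrained":
        raise ValueError(
            "no pretrained weight source is bundled; use weights_mode='random'")
    if weights_mode != "random":
        raise ValueError(f"unknown weights_mode {weights_mode!r}")
    return ModelHandle("frozen-vgg", spec, n_branches=3, one_dim=False,
                       seed=seed, freeze_branches=True)


@dataclass
class TrainedModel:
    """A trained handle plus its training history and config fingerprint."""

    tag: str
    handle: ModelHandle
    history: list[float]
    config: TrainConfig
    config_hash: str = field(default="")

    def __post_init__(self) -> None:
        if not self.config_hash:
            payload = {"tag": self.tag, "spec": asdict(self.handle.spec),
                       "config": asdict(self.config)}
            self.config_hash = hashlib.sha256(
                json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def labels_to_indices(labels) -> np.ndarray:
    idx = np.array([CLASSES.index(lbl) for lbl in labels], dtype=np.int64)
    return idx


def train_model(handle: ModelHandle, x: np.ndarray, labels,
                config: TrainConfig) -> TrainedModel:
    """SGD training on two-class cross-entropy.

    ``labels`` are "stressed"/"relaxed" strings (or 0/1 indices in
    :data:`CLASSES` order).  Shuffling is seeded by ``config.seed``;
    weight initialization is seeded at build time, so the builder seed and
    the train seed together fully determine the result.
    """
    x = np.asarray(x, dtype=DTYPE)
    if len(x) == 0:
        raise ValueError("empty training set")
    if isinstance(labels[0], str):
        y = labels_to_indices(labels)
    else:
        y = np.asarray(labels, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(config.seed)
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), config.batch_size):
            batch = order[start:start + config.batch_size]
            logits = handle.forward(x[batch])
            loss, dlogits = nn.cross_entropy(logits, y[batch])
            handle.backward(dlogits)
            nn.sgd_step(handle.modules(), config.learning_rate)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return TrainedModel(tag=handle.tag, handle=handle, history=history,
                        config=config)


def predict_proba(model: TrainedModel | ModelHandle,
                  x: np.ndarray) -> np.ndarray:
    """Per-sample class probabilities in :data:`CLASSES` order."""
    handle = model.handle if isinstance(model, TrainedModel) else model
    return handle.predict_proba(x)


def snapshot(handle: ModelHandle) -> list[np.ndarray]:
    """Deep copy of every parameter array (for freeze/identity checks)."""
    return copy.deepcopy(handle.state())
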