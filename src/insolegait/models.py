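"""Single- and multi-modal 1-D convolutional gait classifiers.

Each sensor array (pressure, accel, gyro) gets its own convolutional
feature extractor: three valid-padding conv layers of 32, 64 and 128
filters with filter height 20 frames, the first layer spanning the full
sensor width W, later layers running along time only.  Activations are
ReLU followed by batch normalization.  The flattened third-layer feature
map feeds a two-hidden-layer fully connected network with dropout before
a 7-way softmax output.

The first-layer stride follows the steps-per-sample count k: stride 1 for
k in {1, 2} and 2 for k in {3, 4, 5}, so deeper inputs are downsampled
without pooling layers.

A multi-modal classifier concatenates the flattened conv features of two
or three independently trained single-modal networks (conv stacks frozen)
and trains a fresh fully connected head on the fused feature vector; a
joint end-to-end variant is available by fusing untrained stacks.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .preprocess import DEFAULT_T, GaitSample, stack_samples
from .records import MODALITY_WIDTHS

__all__ = [
    "ConvLayerSpec",
    "ModelSpec",
    "TrainConfig",
    "GaitNetwork",
    "conv_output_length",
    "build_single_modal",
    "build_multi_modal",
    "train_model",
    "predict",
    "extract_features",
]

N_CLASSES = 7


def conv_output_length(input_len: int, H: int, s: int) -> int:
    """Number of valid filter positions along an axis of ``input_len``.

    Valid (unpadded) convolution: floor((input_len - H) / s) + 1.
    """
    if H < 1 or s < 1:
        raise ValueError("filter height and stride must be >= 1")
    if input_len < H:
        raise ValueError(
            f"input length {input_len} is shorter than the filter height {H}"
        )
    return (input_len - H) // s + 1


@dataclass
class ConvLayerSpec:
    """One convolution layer: f filters of height H, stride s, ReLU + BN."""

    n_filters: int
    filter_height: int = 20
    stride: int = 1
    batch_norm: bool = True

    def __post_init__(self):
        if self.n_filters < 1 or self.filter_height < 1 or self.stride < 1:
            raise ValueError("filter count, height and stride must be >= 1")


def default_conv_stack(k: int) -> list[ConvLayerSpec]:
    """The 32/64/128-filter stack with the k-dependent first-layer stride."""
    s1 = 1 if k <= 2 else 2
    return [
        ConvLayerSpec(32, 20, s1),
        ConvLayerSpec(64, 20, 1),
        ConvLayerSpec(128, 20, 1),
    ]


@dataclass
class ModelSpec:
    """Hyperparameters of one classifier (single- or multi-modal)."""

    modalities: tuple  # subset of ("pressure", "accel", "gyro")
    k: int = 1
    t: int = DEFAULT_T
    conv_layers: list = None  # default: 32/64/128 stack for this k
    fc_hidden: tuple = (256, 128)
    dropout: float = 0.5
    n_classes: int = N_CLASSES
    split_feet: bool = False  # accel/gyro as two 3-wide branches (W=3)

    def __post_init__(self):
        self.modalities = tuple(self.modalities)
        if not self.modalities or any(m not in MODALITY_WIDTHS for m in self.modalities):
            raise ValueError(f"modalities must be a non-empty subset of {list(MODALITY_WIDTHS)}")
        if len(set(self.modalities)) != len(self.modalities):
            raise ValueError("duplicate modality")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.conv_layers is None:
            self.conv_layers = default_conv_stack(self.k)
        if len(self.fc_hidden) != 2:
            raise ValueError("the fully connected network has exactly two hidden layers")

    @property
    def input_height(self) -> int:
        return self.t * self.k

    def branch_slices(self, modality: str) -> list[slice]:
        if self.split_feet and modality in ("accel", "gyro"):
            return [slice(0, 3), slice(3, 6)]
        return [slice(0, MODALITY_WIDTHS[modality])]

    def feature_length(self) -> int:
        """Flattened conv feature length per branch chain (one branch)."""
        n = self.input_height
        for layer in self.conv_layers:
            n = conv_output_length(n, layer.filter_height, layer.stride)
        return n * self.conv_layers[-1].n_filters


@dataclass
class TrainConfig:
    """Optimization settings: Adam on categorical cross-entropy."""

    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 50
    seed: int = 0
    early_stopping: bool = False
    validation_fraction: float = 0.1
    patience: int = 5

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch size and epochs must be >= 1")


class _Branch:
    """One conv stack applied to a column slice of one modality array."""

    def __init__(self, modality: str, cols: slice, stack: nn.Sequential, feat_len: int):
        self.modality = modality
        self.cols = cols
        self.stack = stack
        self.feat_len = feat_len

    @property
    def frozen(self) -> bool:
        return self.stack.frozen


class GaitNetwork:
    """A set of conv branches feeding one fully connected softmax head."""

    def __init__(self, branches: list, head: nn.Sequential, spec: ModelSpec):
        self.branches = branches
        self.head = head
        self.spec = spec

    @property
    def modalities(self) -> tuple:
        return tuple(dict.fromkeys(b.modality for b in self.branches))

    def _branch_inputs(self, X: dict):
        for b in self.branches:
            if b.modality not in X:
                raise ValueError(f"samples are missing the {b.modality!r} modality")
            yield b, X[b.modality][:, :, b.cols]

    def _features(self, X: dict, train: bool) -> np.ndarray:
        feats = []
        for b, xb in self._branch_inputs(X):
            feats.append(b.stack.forward(xb, train and not b.frozen))
        return np.concatenate(feats, axis=1)

    def forward(self, X: dict, train: bool) -> np.ndarray:
        return self.head.forward(self._features(X, train), train)

    def backward(self, dlogits: np.ndarray) -> None:
        dfeat = self.head.backward(dlogits)
        offset = 0
        for b in self.branches:
            seg = dfeat[:, offset : offset + b.feat_len]
            if not b.frozen:
                b.stack.backward(seg)
            offset += b.feat_len

    def params(self) -> list:
        out = []
        for b in self.branches:
            out.extend(b.stack.params())
        out.extend(self.head.params())
        return out

    def grads(self) -> list:
        out = []
        for b in self.branches:
            out.extend(b.stack.grads())
        out.extend(self.head.grads())
        return out

    def predict_proba(self, X: dict) -> np.ndarray:
        return nn.softmax(self.forward(X, train=False))


def _build_branch(modality: str, cols: slice, spec: ModelSpec, rng) -> _Branch:
    in_ch = cols.stop - cols.start
    layers: list = []
    n = spec.input_height
    for layer_spec in spec.conv_layers:
        layers.append(
            nn.Conv1d(in_ch, layer_spec.n_filters, layer_spec.filter_height, layer_spec.stride, rng)
        )
        layers.append(nn.ReLU())
        if layer_spec.batch_norm:
            # the stated ordering: normalization after the activation
            layers.append(nn.BatchNorm(layer_spec.n_filters))
        n = conv_output_length(n, layer_spec.filter_height, layer_spec.stride)
        in_ch = layer_spec.n_filters
    layers.append(nn.Flatten())
    return _Branch(modality, cols, nn.Sequential(layers), n * in_ch)


def _build_head(in_features: int, spec: ModelSpec, rng) -> nn.Sequential:
    h1, h2 = spec.fc_hidden
    return nn.Sequential(
        [
            nn.Dense(in_features, h1, rng),
            nn.ReLU(),
            nn.Dense(h1, h2, rng),
            nn.ReLU(),
            nn.Dropout(spec.dropout, rng),
            nn.Dense(h2, spec.n_classes, rng),
        ]
    )


def build_single_modal(spec: ModelSpec, seed: int = 0) -> GaitNetwork:
    """Build an (untrained) single-modality classifier from its spec."""
    if len(spec.modalities) != 1:
        raise ValueError("single-modal spec must name exactly one modality")
    rng = np.random.default_rng(seed)
    modality = spec.modalities[0]
    branches = [_build_branch(modality, cols, spec, rng) for cols in spec.branch_slices(modality)]
    head = _build_head(sum(b.feat_len for b in branches), spec, rng)
    return GaitNetwork(branches, head, spec)


def build_multi_modal(
    specs: list,
    pretrained: list | None = None,
    seed: int = 0,
    freeze: bool = True,
) -> GaitNetwork:
    """Fuse 2–3 single-modality networks into one classifier.

    With ``pretrained`` networks (the standard two-stage recipe) their conv
    stacks are copied and frozen, and only the new fully connected head is
    trained on the concatenated features.  Without ``pretrained`` the fused
    network is initialized fresh for end-to-end joint training.
    """
    if not 2 <= len(specs) <= 3:
        raise ValueError("multi-modal fusion takes 2 or 3 single-modality specs")
    ks = {s.k for s in specs}
    ncs = {s.n_classes for s in specs}
    if len(ks) != 1 or len(ncs) != 1:
        raise ValueError("fused specs must share k and n_classes")
    mods = [s.modalities[0] for s in specs]
    if len(set(mods)) != len(mods):
        raise ValueError("fused specs must cover distinct modalities")
    if pretrained is not None and len(pretrained) != len(specs):
        raise ValueError("one pretrained network per spec is required")

    rng = np.random.default_rng(seed)
    branches: list = []
    if pretrained is not None:
        for net in pretrained:
            for b in net.branches:
                b2 = _Branch(b.modality, b.cols, copy.deepcopy(b.stack), b.feat_len)
                b2.stack.frozen = freeze
                branches.append(b2)
    else:
        for spec in specs:
            m = spec.modalities[0]
            branches.extend(_build_branch(m, cols, spec, rng) for cols in spec.branch_slices(m))

    fused_spec = ModelSpec(
        modalities=tuple(mods),
        k=specs[0].k,
        t=specs[0].t,
        conv_layers=specs[0].conv_layers,
        fc_hidden=specs[0].fc_hidden,
        dropout=specs[0].dropout,
        n_classes=specs[0].n_classes,
    )
    head = _build_head(sum(b.feat_len for b in branches), fused_spec, rng)
    return GaitNetwork(branches, head, fused_spec)


def _as_arrays(data) -> tuple[dict, np.ndarray]:
    if isinstance(data, tuple):
        return data
    if data and isinstance(data[0], GaitSample):
        return stack_samples(list(data))
    raise TypeError("expected (X, y) arrays or a non-empty list of GaitSample")


def _batched_features(network: GaitNetwork, X: dict, batch: int = 256) -> np.ndarray:
    n = next(iter(X.values())).shape[0]
    parts = []
    for i in range(0, n, batch):
        Xi = {m: a[i : i + batch] for m, a in X.items()}
        parts.append(network._features(Xi, train=False))
    return np.concatenate(parts, axis=0)


def train_model(network: GaitNetwork, train_data, config: TrainConfig):
    """Train with Adam on categorical cross-entropy; returns loss history.

    Deterministic given ``config.seed`` (batch order, dropout masks).  When
    every conv branch is frozen (fused multi-modal stage) features are
    precomputed once and only the head is optimized.  Optional early
    stopping monitors loss on a held-out fraction of the training set.
    """
    X, y = _as_arrays(train_data)
    n = len(y)
    if n == 0:
        raise ValueError("empty training set")
    n_classes = network.spec.n_classes
    rng = np.random.default_rng(config.seed)

    val_idx = np.array([], dtype=int)
    fit_idx = np.arange(n)
    if config.early_stopping and n >= 10:
        perm = rng.permutation(n)
        n_val = max(1, int(round(config.validation_fraction * n)))
        val_idx, fit_idx = perm[:n_val], perm[n_val:]

    head_only = all(b.frozen for b in network.branches)
    if head_only:
        F = _batched_features(network, X)
        forward = lambda idx, train: network.head.forward(F[idx], train)
        backward = network.head.backward
    else:
        forward = lambda idx, train: network.forward(
            {m: a[idx] for m, a in X.items() if m in network.modalities}, train
        )
        backward = network.backward

    opt = nn.Adam(network.params(), lr=config.learning_rate)
    history: list[float] = []
    best_val, since_best = np.inf, 0
    for _epoch in range(config.epochs):
        order = fit_idx[rng.permutation(len(fit_idx))]
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = forward(idx, True)
            probs = nn.softmax(logits)
            losses.append(nn.cross_entropy(probs, y[idx]))
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(idx)), y[idx]] = 1.0
            backward((probs - onehot) / len(idx))
            opt.step(network.grads())
        history.append(float(np.mean(losses)))
        if len(val_idx):
            val_probs = nn.softmax(forward(val_idx, False))
            val_loss = nn.cross_entropy(val_probs, y[val_idx])
            if val_loss < best_val - 1e-6:
                best_val, since_best = val_loss, 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
    return network, history


def predict(network: GaitNetwork, data) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels (ties -> lowest class code)."""
    X, _ = _as_arrays(data) if not isinstance(data, dict) else (data, None)
    probs = network.predict_proba(X)
    return probs, probs.argmax(axis=1)


def extract_features(network: GaitNetwork, data) -> np.ndarray:
    """Post-flatten, pre-FC conv features of a single-modality network."""
    if len(network.modalities) != 1:
        raise ValueError("features are per-modality; pass a single-modal network")
    X, _ = _as_arrays(data) if not isinstance(data, dict) else (data, None)
    return _batched_features(network, X)
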