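"""Evaluation protocols: repeated random subsampling and K-fold CV.

Two protocols are provided, matching common practice for small wearable
datasets: (a) repeated random subsampling — draw disjoint train/test sets
of fixed size (1000/1000 by default), repeat 20 times; (b) K-fold cross
validation with K equal to the number of classes (7), repeated 10 times
with fresh shuffles.  Inside every split the feature standardization is
refit on the training portion only, so no test statistics leak into the
transform.

``run_experiment`` drives the full loop for one (modality combination, k)
cell: split, standardize, train single-modal networks, optionally fuse,
predict, score, and aggregate accuracies and a pooled confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .models import (
    ModelSpec,
    TrainConfig,
    build_multi_modal,
    build_single_modal,
    predict,
    train_model,
)
from .preprocess import GaitSample, standardize

__all__ = [
    "ProtocolConfig",
    "ExperimentResult",
    "split_kfold",
    "split_random_subsample",
    "evaluate_accuracy",
    "run_experiment",
    "fit_and_score",
]


@dataclass
class ProtocolConfig:
    """Which protocol to run and at what size."""

    protocol: str = "random_subsample"  # or "kfold"
    n_train: int = 1000
    n_test: int = 1000
    repetitions: int = 20  # the K-fold protocol conventionally uses 10
    K: int = 7
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if self.protocol not in ("random_subsample", "kfold"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class ExperimentResult:
    """Per-repetition accuracies plus pooled summary for one experiment."""

    accuracies: list
    confusion: np.ndarray  # (n_classes, n_classes) pooled counts
    modalities: tuple
    k: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=0)) if len(self.accuracies) > 1 else 0.0


def split_kfold(n: int, K: int, seed: int) -> list[np.ndarray]:
    """Random partition of ``range(n)`` into K folds of near-equal size.

    Fold sizes are floor(n/K) or ceil(n/K); every index appears in exactly
    one fold.  For fold i the training set is the union of the other folds.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if n < K:
        raise ValueError(f"cannot split {n} samples into {K} folds")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, K)]


def _stratified_draw(rng, labels: np.ndarray, pool: np.ndarray, size: int) -> np.ndarray:
    """Draw ``size`` indices from ``pool`` with per-class proportional counts."""
    classes = np.unique(labels[pool])
    picks = []
    remaining = size
    for j, c in enumerate(classes):
        cand = pool[labels[pool] == c]
        take = round(size * len(cand) / len(pool)) if j < len(classes) - 1 else remaining
        take = min(int(take), len(cand), remaining)
        picks.append(rng.choice(cand, size=take, replace=False))
        remaining -= take
    out = np.concatenate(picks)
    if remaining > 0:  # rounding shortfall: top up from the untouched pool
        rest = np.setdiff1d(pool, out)
        out = np.concatenate([out, rng.choice(rest, size=remaining, replace=False)])
    return out


def split_random_subsample(
    n: int,
    n_train: int,
    n_test: int,
    repetitions: int,
    seed: int,
    labels: np.ndarray | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint train/test index draws without replacement, repeated.

    With ``labels`` provided the draws are stratified by class.  Each
    repetition uses an independently derived seed, so the list is
    reproducible from the master seed.
    """
    if n_train + n_test > n:
        raise ValueError(
            f"cannot draw {n_train}+{n_test} distinct samples from {n}"
        )
    seeds = np.random.SeedSequence(seed).generate_state(repetitions) % (2**31)
    splits = []
    for s in seeds:
        rng = np.random.default_rng(int(s))
        if labels is None:
            perm = rng.permutation(n)
            train, test = perm[:n_train], perm[n_train : n_train + n_test]
        else:
            all_idx = np.arange(n)
            train = _stratified_draw(rng, labels, all_idx, n_train)
            rest = np.setdiff1d(all_idx, train)
            test = _stratified_draw(rng, labels, rest, n_test)
        splits.append((np.sort(train), np.sort(test)))
    return splits


def evaluate_accuracy(predicted: np.ndarray, true: np.ndarray) -> float:
    """Fraction of predictions matching the true labels."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {true.shape}")
    if predicted.size == 0:
        raise ValueError("cannot score empty label arrays")
    return float(np.mean(predicted == true))


def fit_and_score(
    train_samples: list[GaitSample],
    test_samples: list[GaitSample],
    modalities: tuple,
    train_config: TrainConfig,
    model_kwargs: dict | None = None,
    seed: int = 0,
) -> tuple[float, np.ndarray, dict]:
    """Standardize, train (fusing if multi-modal), and score one split.

    Returns (test accuracy, confusion-matrix counts, trained networks by
    modality plus ``"fused"`` when applicable).
    """
    model_kwargs = dict(model_kwargs or {})
    k = train_samples[0].k
    t = train_samples[0].t
    train_std, test_std, _ = standardize(train_samples, test_samples)
    y_true = np.array([int(s.label) for s in test_samples])

    nets: dict = {}
    seeds = np.random.SeedSequence(seed).generate_state(len(modalities) + 1) % (2**31)
    for m, s in zip(modalities, seeds):
        spec = ModelSpec(modalities=(m,), k=k, t=t, **model_kwargs)
        net = build_single_modal(spec, seed=int(s))
        cfg = TrainConfig(**{**train_config.__dict__, "seed": int(s)})
        train_model(net, train_std, cfg)
        nets[m] = net

    if len(modalities) == 1:
        final = nets[modalities[0]]
    else:
        specs = [nets[m].spec for m in modalities]
        fused = build_multi_modal(
            specs, pretrained=[nets[m] for m in modalities], seed=int(seeds[-1])
        )
        cfg = TrainConfig(**{**train_config.__dict__, "seed": int(seeds[-1])})
        train_model(fused, train_std, cfg)
        nets["fused"] = fused
        final = fused

    _, y_pred = predict(final, test_std)
    acc = evaluate_accuracy(y_pred, y_true)
    n_classes = final.spec.n_classes
    conf = _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))
    return acc, conf, nets


def run_experiment(
    samples: list[GaitSample],
    protocol: ProtocolConfig,
    modalities: tuple,
    train_config: TrainConfig | None = None,
    model_kwargs: dict | None = None,
) -> ExperimentResult:
    """Run one evaluation cell: all repetitions of one protocol.

    For the subsampling protocol each repetition contributes one accuracy;
    for K-fold each fold of each repetition contributes one.  The confusion
    matrix pools every test prediction made.
    """
    train_config = train_config or TrainConfig()
    labels = np.array([int(s.label) for s in samples])
    n = len(samples)
    k = samples[0].k
    accs: list[float] = []
    conf = None
    rep_seeds = np.random.SeedSequence(protocol.seed).generate_state(protocol.repetitions) % (2**31)

    def one_split(train_idx, test_idx, seed):
        nonlocal conf
        acc, c, _ = fit_and_score(
            [samples[i] for i in train_idx],
            [samples[i] for i in test_idx],
            modalities,
            train_config,
            model_kwargs,
            seed=seed,
        )
        accs.append(acc)
        conf = c if conf is None else conf + c

    if protocol.protocol == "random_subsample":
        splits = split_random_subsample(
            n,
            protocol.n_train,
            protocol.n_test,
            protocol.repetitions,
            protocol.seed,
            labels=labels if protocol.stratified else None,
        )
        for (train_idx, test_idx), s in zip(splits, rep_seeds):
            one_split(train_idx, test_idx, int(s))
    else:
        for s in rep_seeds:
            if protocol.stratified:
                folds = _stratified_kfold(labels, protocol.K, int(s))
            else:
                folds = split_kfold(n, protocol.K, int(s))
            for i, test_idx in enumerate(folds):
                train_idx = np.setdiff1d(np.arange(n), test_idx)
                one_split(train_idx, test_idx, int(s) + i)

    return ExperimentResult(
        accuracies=accs, confusion=conf, modalities=tuple(modalities), k=k
    )


def _stratified_kfold(labels: np.ndarray, K: int, seed: int) -> list[np.ndarray]:
    """Class-stratified K folds; per class the fold counts differ by <= 1."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(K)]
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        for j, part in enumerate(np.array_split(idx, K)):
            folds[j].extend(part.tolist())
    return [np.sort(np.array(f, dtype=int)) for f in folds]
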