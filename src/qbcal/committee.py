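"""Committee construction and forward-only probability profiling.

A committee is M copies of the same classifier trained on the same
labeled seed subset under different learning rates; where the members
disagree, the sample is informative. The classifier contract is
deliberately small — ``fit`` and ``predict_proba`` — so a deep CNN
adapter can stand in for the bundled pixel-level softmax model without
touching the rest of the framework. Profiling the unlabeled pool is a
pure forward pass: labels are never read.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol, Sequence, runtime_checkable

import h5py
import numpy as np
import yaml
from sklearn.metrics import roc_auc_score

from .errors import NotFittedError, ValidationError
from .pipeline import SliceDataset
from .scoring import CommitteeProfile

#: the three fine-tuning learning rates used to diversify the committee
DEFAULT_LEARNING_RATES = (0.001, 0.0005, 0.0001)


@dataclass(frozen=True)
class TrainingConfig:
    """SGD hyperparameters; defaults follow the study's grid-searched values."""

    learning_rate: float = 0.001
    max_epochs: int = 30
    batch_size: int = 16
    momentum: float = 0.8
    l2_penalty: float = 0.0001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError(f"learning_rate must be positive, got {self.learning_rate}")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValidationError("max_epochs and batch_size must be positive integers")
        if not 0 <= self.momentum < 1:
            raise ValidationError(f"momentum must be in [0, 1), got {self.momentum}")
        if self.l2_penalty < 0:
            raise ValidationError(f"l2_penalty must be non-negative, got {self.l2_penalty}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainingConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown TrainingConfig keys {sorted(unknown)}; known: {sorted(known)}")
        return cls(**data)


@runtime_checkable
class TrainableProbabilisticClassifier(Protocol):
    """Behavioral contract every committee member must satisfy."""

    def fit(self, dataset: SliceDataset, config: TrainingConfig,
            validation: SliceDataset | None = None) -> "TrainableProbabilisticClassifier": ...

    def predict_proba(self, dataset: SliceDataset) -> np.ndarray: ...


class PixelSoftmaxClassifier:
    """Multinomial logistic regression over flattened, channel-concatenated pixels.

    Trained by minibatch SGD with classical momentum and an L2 penalty on
    the weights (not the bias), exactly as parameterized by
    :class:`TrainingConfig`. Weights start at zero, so given identical
    data, config and seed the fit is bitwise reproducible; with a
    validation set supplied, the epoch checkpoint with the highest
    validation ROC-AUC is kept (early stopping at the best epoch).

    This is the framework's desk-scale reference member. Like the
    fine-tuned CNNs it stands in for, it supports warm-starting from an
    already-trained model (:meth:`init_from`): committee members that
    share a warm start differ only by the small learning-rate-dependent
    updates made on top of it, which is what makes their disagreement
    concentrate on genuinely ambiguous samples rather than on how far
    each member's weights have grown.
    """

    def __init__(self) -> None:
        self.weights_: np.ndarray | None = None
        self.bias_: np.ndarray | None = None
        self.classes_: np.ndarray | None = None
        self.config_: TrainingConfig | None = None
        self._init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    def init_from(self, other: "PixelSoftmaxClassifier") -> "PixelSoftmaxClassifier":
        """Use a fitted model's parameters as this model's starting point."""
        if other.weights_ is None or other.bias_ is None or other.classes_ is None:
            raise NotFittedError("init_from requires a fitted model")
        self._init = (other.weights_.copy(), other.bias_.copy(), other.classes_.copy())
        return self

    # -- training ----------------------------------------------------------
    def fit(self, dataset: SliceDataset, config: TrainingConfig,
            validation: SliceDataset | None = None) -> "PixelSoftmaxClassifier":
        X = dataset.features()
        y = dataset.labels
        classes = np.unique(y)
        if classes.size < 2:
            raise ValidationError(f"training set contains a single class {classes.tolist()}; need >= 2")
        class_index = {c: i for i, c in enumerate(classes.tolist())}
        yi = np.array([class_index[c] for c in y.tolist()])
        n, d = X.shape
        c = classes.size
        if self._init is not None:
            W0, b0, cls0 = self._init
            if W0.shape != (d, c) or not np.array_equal(cls0, classes):
                raise ValidationError(
                    f"warm-start parameters (shape {W0.shape}, classes {cls0.tolist()}) do not match "
                    f"the training data (d={d}, classes {classes.tolist()})"
                )
            W, b = W0.copy(), b0.copy()
        else:
            W = np.zeros((d, c))
            b = np.zeros(c)
        vW = np.zeros_like(W)
        vb = np.zeros_like(b)
        rng = np.random.default_rng(config.seed)
        onehot = np.eye(c)[yi]
        best: tuple[float, np.ndarray, np.ndarray] | None = None
        for _epoch in range(config.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, config.batch_size):
                idx = order[start:start + config.batch_size]
                Xb, Yb = X[idx], onehot[idx]
                P = _softmax(Xb @ W + b)
                err = (P - Yb) / len(idx)
                gW = Xb.T @ err + config.l2_penalty * W
                gb = err.sum(axis=0)
                vW = config.momentum * vW - config.learning_rate * gW
                vb = config.momentum * vb - config.learning_rate * gb
                W = W + vW
                b = b + vb
            if validation is not None:
                probs = _softmax(validation.features() @ W + b)
                auc = roc_auc_score(validation.labels, probs[:, -1])
                if best is None or auc > best[0]:
                    best = (float(auc), W.copy(), b.copy())
        if best is not None:
            _, W, b = best
        self.weights_, self.bias_, self.classes_, self.config_ = W, b, classes, config
        return self

    # -- inference ---------------------------------------------------------
    def predict_proba(self, dataset: SliceDataset) -> np.ndarray:
        if self.weights_ is None or self.bias_ is None:
            raise NotFittedError("PixelSoftmaxClassifier.predict_proba called before fit")
        X = dataset.features()
        if X.shape[1] != self.weights_.shape[0]:
            raise ValidationError(
                f"feature dimension {X.shape[1]} does not match fitted model ({self.weights_.shape[0]})"
            )
        return _softmax(X @ self.weights_ + self.bias_)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        if self.weights_ is None:
            raise NotFittedError("cannot save an unfitted classifier")
        with h5py.File(path, "w") as f:
            f.create_dataset("weights", data=self.weights_)
            f.create_dataset("bias", data=self.bias_)
            f.create_dataset("classes", data=self.classes_)
            for k, v in dataclasses.asdict(self.config_).items():
                f.attrs[k] = v

    @classmethod
    def load(cls, path: str | Path) -> "PixelSoftmaxClassifier":
        clf = cls()
        with h5py.File(path, "r") as f:
            clf.weights_ = np.asarray(f["weights"][...])
            clf.bias_ = np.asarray(f["bias"][...])
            clf.classes_ = np.asarray(f["classes"][...])
            clf.config_ = TrainingConfig(**{k: f.attrs[k].item() if hasattr(f.attrs[k], "item") else f.attrs[k]
                                            for k in f.attrs})
        return clf


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def reference_classifier() -> PixelSoftmaxClassifier:
    """Factory for the bundled pixel-level softmax committee member."""
    return PixelSoftmaxClassifier()


@dataclass
class Committee:
    """M trained members plus the configs that produced them."""

    members: list[TrainableProbabilisticClassifier]
    configs: list[TrainingConfig]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValidationError(f"committee needs >= 2 members, got {len(self.members)}")
        if len(self.members) != len(self.configs):
            raise ValidationError("one config per member required")

    @property
    def n_members(self) -> int:
        return len(self.members)


def build_committee(
    labeled_subset: SliceDataset,
    base_classifier: Callable[[], TrainableProbabilisticClassifier] = reference_classifier,
    learning_rates: Sequence[float] = DEFAULT_LEARNING_RATES,
    config: TrainingConfig = TrainingConfig(),
    validation: SliceDataset | None = None,
    pretrained: TrainableProbabilisticClassifier | None = None,
    shared_init: bool = True,
) -> Committee:
    """Train one member per learning rate on the same labeled seed subset.

    Members differ only by learning rate (and, per the seed policy, by a
    per-member seed offset ``config.seed + index`` that keeps each member
    individually reproducible). Member order follows ``learning_rates``.

    Mirroring the transfer-learning design, every member fine-tunes from
    the same starting parameters: ``pretrained`` if given, otherwise
    (with ``shared_init``) a base model first trained on the labeled
    subset under ``config``. With ``shared_init=False`` and no
    ``pretrained`` model, members train from scratch. Warm-starting needs
    the classifier to expose ``init_from``; classifiers without it train
    from their own initialization.
    """
    if len(learning_rates) < 2:
        raise ValidationError(f"need >= 2 learning rates for a committee, got {list(learning_rates)}")
    if any(lr <= 0 for lr in learning_rates):
        raise ValidationError("learning rates must be positive")
    if len(labeled_subset) == 0:
        raise ValidationError("labeled subset is empty")
    if np.unique(labeled_subset.labels).size < 2:
        raise ValidationError("labeled subset contains a single class; committee training is degenerate")
    if pretrained is None and shared_init:
        pretrained = base_classifier()
        pretrained.fit(labeled_subset, config, validation=validation)
    members, configs = [], []
    for i, lr in enumerate(learning_rates):
        cfg = dataclasses.replace(config, learning_rate=float(lr), seed=config.seed + i)
        clf = base_classifier()
        if pretrained is not None and hasattr(clf, "init_from"):
            clf.init_from(pretrained)
        clf.fit(labeled_subset, cfg, validation=validation)
        members.append(clf)
        configs.append(cfg)
    return Committee(members, configs)


def predict_profiles(committee: Committee, pool: SliceDataset) -> list[CommitteeProfile]:
    """Forward-only committee pass over the pool; one profile per sample.

    Only pixel data is read — the pool may carry no labels at all.
    """
    if len(pool) == 0:
        raise ValidationError("pool is empty")
    per_member = [np.asarray(m.predict_proba(pool)) for m in committee.members]
    n = len(pool)
    for j, probs in enumerate(per_member):
        if probs.shape[0] != n:
            raise ValidationError(f"member {j} returned {probs.shape[0]} rows for a pool of {n}")
    stacked = np.stack(per_member, axis=0)  # (M, N, C)
    ids = pool.sample_ids
    return [CommitteeProfile(ids[i], stacked[:, i, :]) for i in range(n)]
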