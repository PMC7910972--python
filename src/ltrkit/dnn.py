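"""Lineage classifiers: a fully connected and a convolutional network.

Both consume the (scaled, PCA-reduced) k-mer feature vector of an element
and emit per-lineage probabilities over the canonical class list.

FNN: three hidden layers of 200 ReLU units, softmax output trained with
mean-squared error on one-hot targets, Adam (lr 0.001, beta1 0.9,
beta2 0.999, eps 1e-8), mini-batches of 128; SGD (lr 0.01) available by
config.  CNN: the feature vector as a 1-channel 1-D signal through three
conv layers of 100/150/225 filters (kernel 3), max-pool 2 after each,
dropout 0.5 after the last conv, a 128-unit dense layer and a softmax
output, trained with categorical cross-entropy and Adam (lr 0.001).
Training runs a fixed number of epochs (default 25) with no early
stopping; the best-validation-F1 weights are retained.
"""

from __future__ import annotations

import logging
import pickle
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._nn import (
    SGD,
    Adam,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    Loss,
    MaxPool1D,
    Network,
    ReLU,
    Reshape1D,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HyperParams:
    """Training hyper-parameters shared by both architectures."""

    hidden_layers: tuple[int, ...] = (200, 200, 200)  # FNN
    conv_filters: tuple[int, ...] = (100, 150, 225)  # CNN
    kernel_size: int = 3
    pool_size: int = 2
    dropout: float = 0.5
    dense_units: int = 128
    fnn_loss: str = "mse"  # on one-hot targets; "categorical_crossentropy" available
    cnn_loss: str = "categorical_crossentropy"
    optimizer: str = "adam"  # or "sgd"
    learning_rate: float = 0.001
    sgd_learning_rate: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 128
    epochs: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("learning rate and batch size must be positive")


@dataclass
class Split:
    """Disjoint stratified train/validation/test index sets."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def __iter__(self):
        return iter((self.train, self.val, self.test))


def split_dataset(
    labels: Sequence[str] | np.ndarray,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> Split:
    """Stratified 80/10/10 split (by default), deterministic under seed.

    Classes with fewer than 3 members cannot be stratified; their members
    are placed by a proportional random draw (with a warning).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions {fractions} do not sum to 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    parts: list[list[np.ndarray]] = [[], [], []]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n = idx.size
        if n < 3:
            warnings.warn(
                f"class {cls!r} has only {n} members; falling back to "
                "non-stratified placement", stacklevel=2,
            )
            for i in idx:
                bucket = rng.choice(3, p=fractions)
                parts[bucket].append(np.array([i]))
            continue
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        n_train = min(n_train, n - 2)
        n_val = max(1, min(n_val, n - n_train - 1))
        parts[0].append(idx[:n_train])
        parts[1].append(idx[n_train : n_train + n_val])
        parts[2].append(idx[n_train + n_val :])
    out = []
    for chunk in parts:
        arr = np.concatenate(chunk) if chunk else np.array([], dtype=int)
        out.append(np.sort(arr))
    split = Split(*out)
    total = len(split.train) + len(split.val) + len(split.test)
    assert total == len(labels), "split does not cover all rows"
    return split


def build_fnn(input_dim: int, n_classes: int, hp: HyperParams = HyperParams()) -> Network:
    """Fully connected net: [input_dim, 200, 200, 200, n_classes] with ReLU."""
    if input_dim < 1 or n_classes < 2:
        raise ValueError("need input_dim >= 1 and n_classes >= 2")
    rng = np.random.default_rng(hp.seed)
    layers: list = []
    widths = [input_dim, *hp.hidden_layers]
    for n_in, n_out in zip(widths[:-1], widths[1:]):
        layers.append(Dense(n_in, n_out, rng))
        layers.append(ReLU())
    layers.append(Dense(widths[-1], n_classes, rng, scale="glorot"))
    net = Network(layers, Loss(hp.fnn_loss))
    net.architecture = "FNN"
    net.input_dim = input_dim
    net.hp = hp
    return net


def _cnn_output_length(input_dim: int, hp: HyperParams) -> int:
    L = input_dim
    for _ in hp.conv_filters:
        L = L - hp.kernel_size + 1
        if L < 1:
            return 0
        L //= hp.pool_size
        if L < 1:
            return 0
    return L


def build_cnn(input_dim: int, n_classes: int, hp: HyperParams = HyperParams()) -> Network:
    """Conv stack 100-150-225 (k=3, pool 2 each), dropout 0.5, dense 128, softmax."""
    if input_dim < 1 or n_classes < 2:
        raise ValueError("need input_dim >= 1 and n_classes >= 2")
    L_out = _cnn_output_length(input_dim, hp)
    if L_out < 1:
        raise ValueError(
            f"input_dim={input_dim} too small for {len(hp.conv_filters)} "
            f"conv(k={hp.kernel_size})+pool({hp.pool_size}) stages"
        )
    rng = np.random.default_rng(hp.seed)
    layers: list = [Reshape1D()]
    c_in = 1
    for c_out in hp.conv_filters:
        layers.append(Conv1D(c_in, c_out, hp.kernel_size, rng))
        layers.append(ReLU())
        layers.append(MaxPool1D(hp.pool_size))
        c_in = c_out
    layers.append(Dropout(hp.dropout, np.random.default_rng(hp.seed + 1)))
    layers.append(Flatten())
    layers.append(Dense(c_in * L_out, hp.dense_units, rng))
    layers.append(ReLU())
    layers.append(Dense(hp.dense_units, n_classes, rng, scale="glorot"))
    net = Network(layers, Loss(hp.cnn_loss))
    net.architecture = "CNN"
    net.input_dim = input_dim
    net.hp = hp
    return net


@dataclass
class TrainedModel:
    """A trained network plus everything needed to classify new elements."""

    network: Network
    classes: list[str]
    history: "np.recarray | None" = None
    pipeline: object | None = None  # fitted FeaturePipeline, when attached
    kmer_normalize: bool = False

    @property
    def architecture(self) -> str:
        return getattr(self.network, "architecture", "?")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(np.asarray(X, dtype=np.float32))

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        return np.asarray(self.classes)[proba.argmax(axis=1)]

    def predict_elements(self, elements) -> tuple[np.ndarray, np.ndarray]:
        """(labels, per-class scores) for raw elements via the attached pipeline."""
        from .kmer_features import FeatureMatrix

        if self.pipeline is None:
            raise RuntimeError("no preprocessing pipeline attached to this model")
        fm = FeatureMatrix.from_elements(elements, normalize=self.kmer_normalize)
        X = self.pipeline.transform(fm.raw)
        proba = self.predict_proba(X)
        return np.asarray(self.classes)[proba.argmax(axis=1)], proba

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "TrainedModel":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, TrainedModel):
            raise TypeError(f"{path} does not contain a TrainedModel")
        return obj

    def history_to_csv(self, path, provenance: str | None = None) -> None:
        with open(path, "w") as fh:
            if provenance:
                fh.write(f"# {provenance}\n")
            fh.write("epoch,train_loss,val_loss,train_f1,val_f1\n")
            for row in self.history:
                fh.write(
                    f"{int(row.epoch)},{row.train_loss:.6f},{row.val_loss:.6f},"
                    f"{row.train_f1:.6f},{row.val_f1:.6f}\n"
                )


def _onehot(y_idx: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((y_idx.size, n_classes), dtype=np.float32)
    out[np.arange(y_idx.size), y_idx] = 1.0
    return out


def _macro_f1(y_true_idx: np.ndarray, y_pred_idx: np.ndarray, n_classes: int) -> float:
    f1s = []
    for c in range(n_classes):
        tp = int(((y_pred_idx == c) & (y_true_idx == c)).sum())
        fp = int(((y_pred_idx == c) & (y_true_idx != c)).sum())
        fn = int(((y_pred_idx != c) & (y_true_idx == c)).sum())
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom else 0.0)
    return float(np.mean(f1s))


def train(
    network: Network,
    X_train: np.ndarray,
    y_train: Sequence[str],
    X_val: np.ndarray,
    y_val: Sequence[str],
    hp: HyperParams | None = None,
) -> TrainedModel:
    """Fixed-epoch mini-batch training; best-epoch weights by validation F1.

    The class list is the sorted union of training and validation labels.
    Raises on a non-finite loss (divergence) rather than continuing.
    """
    hp = hp or getattr(network, "hp", HyperParams())
    classes = sorted(set(map(str, y_train)) | set(map(str, y_val)))
    cls_index = {c: i for i, c in enumerate(classes)}
    yt = np.array([cls_index[str(c)] for c in y_train])
    yv = np.array([cls_index[str(c)] for c in y_val])
    X_train = np.asarray(X_train, dtype=np.float32)
    X_val = np.asarray(X_val, dtype=np.float32)
    n_classes = len(classes)
    Y_train = _onehot(yt, n_classes)
    Y_val = _onehot(yv, n_classes)

    if hp.optimizer == "adam":
        opt = Adam(network.params, lr=hp.learning_rate,
                   beta1=hp.beta1, beta2=hp.beta2, eps=hp.epsilon)
    elif hp.optimizer == "sgd":
        opt = SGD(network.params, lr=hp.sgd_learning_rate)
    else:
        raise ValueError(f"unknown optimizer {hp.optimizer!r}")

    rng = np.random.default_rng(hp.seed)
    rows = []
    best_f1 = -1.0
    best_weights = network.get_weights()
    n = len(X_train)
    for epoch in range(1, hp.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, hp.batch_size):
            batch = order[start : start + hp.batch_size]
            logits = network.forward(X_train[batch], train=True)
            loss, dz = network.loss(logits, Y_train[batch])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss!r}"
                )
            network.backward(dz)
            opt.step(network.grads)
            losses.append(loss)
        p_train = network.predict_proba(X_train)
        p_val = network.predict_proba(X_val)
        train_loss = float(np.mean(losses))
        val_loss, _ = network.loss(np.log(p_val + 1e-12), Y_val)
        train_f1 = _macro_f1(yt, p_train.argmax(axis=1), n_classes)
        val_f1 = _macro_f1(yv, p_val.argmax(axis=1), n_classes)
        rows.append((epoch, train_loss, val_loss, train_f1, val_f1))
        if val_f1 > best_f1:
            best_f1 = val_f1
            best_weights = network.get_weights()
        logger.info(
            "%s epoch %d/%d: train_loss=%.4f val_loss=%.4f train_f1=%.3f val_f1=%.3f",
            getattr(network, "architecture", "?"), epoch, hp.epochs,
            train_loss, val_loss, train_f1, val_f1,
        )
    network.set_weights(best_weights)
    history = np.rec.fromrecords(
        rows, names=["epoch", "train_loss", "val_loss", "train_f1", "val_f1"]
    )
    return TrainedModel(network=network, classes=classes, history=history)


@dataclass
class EvaluationReport:
    """Per-class precision/recall/F1/support with macro and weighted averages."""

    classes: list[str]
    confusion: np.ndarray  # rows = true, cols = predicted
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def weighted_f1(self) -> float:
        return float(np.average(self.f1, weights=self.support)) if self.support.sum() else 0.0

    @property
    def accuracy(self) -> float:
        total = self.confusion.sum()
        return float(np.trace(self.confusion) / total) if total else 0.0

    def to_tsv(self, path, provenance: str | None = None) -> None:
        with open(path, "w") as fh:
            if provenance:
                fh.write(f"# {provenance}\n")
            fh.write("lineage\tprecision\trecall\tf1\tsupport\n")
            for i, cls in enumerate(self.classes):
                fh.write(
                    f"{cls}\t{self.precision[i]:.4f}\t{self.recall[i]:.4f}\t"
                    f"{self.f1[i]:.4f}\t{int(self.support[i])}\n"
                )
            fh.write(f"macro\t{self.macro_precision:.4f}\t{self.macro_recall:.4f}\t"
                     f"{self.macro_f1:.4f}\t{int(self.support.sum())}\n")


def evaluation_report(
    y_true: Sequence[str], y_pred: Sequence[str], classes: Sequence[str]
) -> EvaluationReport:
    """Metrics recomputed from the confusion matrix (first principles)."""
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    unseen = sorted({str(c) for c in y_true} - set(classes))
    if unseen:
        raise ValueError(f"test labels contain classes unknown to the model: {unseen}")
    n = len(classes)
    confusion = np.zeros((n, n), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[index[str(t)], index[str(p)]] += 1
    support = confusion.sum(axis=1)
    pred_totals = confusion.sum(axis=0)
    tp = np.diag(confusion)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_totals > 0, tp / pred_totals, 0.0)
        recall = np.where(support > 0, tp / support, 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    return EvaluationReport(
        classes=classes,
        confusion=confusion,
        precision=precision.astype(float),
        recall=recall.astype(float),
        f1=f1.astype(float),
        support=support,
    )


def evaluate(model: TrainedModel, X_test: np.ndarray, y_test: Sequence[str]) -> EvaluationReport:
    """Evaluate a trained model on held-out features and labels."""
    y_pred = model.predict(X_test)
    return evaluation_report([str(y) for y in y_test], list(y_pred), model.classes)
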