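"""Training loop, evaluation metrics, and subject-wise cross-validation.

The classifier is trained with Adam (initial learning rate 0.001, batches
of 8) to minimize softmax cross-entropy.  After each epoch validation
accuracy is measured; the parameters with the best validation accuracy are
retained and training stops once the validation accuracy has not improved
for ``patience`` epochs.  Splits are by subject, and the trainer refuses to
run if any subject appears in both the training and validation sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from taskcrnn.errors import ConfigError, DataError
from taskcrnn.model import CRNN, CrnnConfig
from taskcrnn.nn import DTYPE, cross_entropy
from taskcrnn.preprocess import DatasetSplit, make_cv_folds

logger = logging.getLogger("taskcrnn")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol."""

    learning_rate: float = 0.001
    batch_size: int = 8
    max_epochs: int = 100
    patience: int = 10
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")


class Adam:
    """Adam optimizer over a model's named parameter arrays."""

    def __init__(self, model: CRNN, config: TrainConfig) -> None:
        self.model = model
        self.cfg = config
        self.t = 0
        self.m = {name: np.zeros_like(layer.params[key]) for name, layer, key in model.named_params()}
        self.v = {name: np.zeros_like(layer.params[key]) for name, layer, key in model.named_params()}

    def step(self) -> None:
        self.t += 1
        c = self.cfg
        bc1 = 1.0 - c.beta1**self.t
        bc2 = 1.0 - c.beta2**self.t
        for name, layer, key in self.model.named_params():
            g = layer.grads[key]
            self.m[name] = c.beta1 * self.m[name] + (1.0 - c.beta1) * g
            self.v[name] = c.beta2 * self.v[name] + (1.0 - c.beta2) * g * g
            m_hat = self.m[name] / bc1
            v_hat = self.v[name] / bc2
            layer.params[key] = (
                layer.params[key] - c.learning_rate * m_hat / (np.sqrt(v_hat) + c.eps)
            ).astype(DTYPE)


@dataclass
class SampleSet:
    """A stacked sample array with labels and per-sample subject ids."""

    X: np.ndarray  # [N, T, X', Y', Z', 1]
    y: np.ndarray  # [N] int
    subjects: np.ndarray  # [N] str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=DTYPE)
        self.y = np.asarray(self.y)
        self.subjects = np.asarray(self.subjects)
        if not (len(self.X) == len(self.y) == len(self.subjects)):
            raise DataError("X, y and subjects must have equal length")

    def __len__(self) -> int:
        return len(self.y)

    def restrict(self, subject_set) -> "SampleSet":
        mask = np.isin(self.subjects, sorted(subject_set))
        return SampleSet(self.X[mask], self.y[mask], self.subjects[mask])

    @classmethod
    def from_samples(cls, samples) -> "SampleSet":
        return cls(
            np.stack([s.data for s in samples]),
            np.array([s.label for s in samples]),
            np.array([s.subject_id for s in samples]),
        )


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy, macro precision/recall/F1, and the confusion matrix.

    Confusion rows are the true class, columns the predicted class.
    Per-class precision/recall are 0 where undefined (no predictions or no
    support for that class).
    """

    confusion: np.ndarray
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: tuple[dict, ...]

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = 7) -> "MetricsReport":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if len(y_true) == 0:
            raise DataError("cannot evaluate an empty sample set")
        cm = np.zeros((n_classes, n_classes), dtype=np.int64)
        np.add.at(cm, (y_true, y_pred), 1)
        tp = np.diag(cm).astype(float)
        support = cm.sum(axis=1).astype(float)
        predicted = cm.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            prec = np.where(predicted > 0, tp / predicted, 0.0)
            rec = np.where(support > 0, tp / support, 0.0)
            f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
        per_class = tuple(
            {
                "precision": float(prec[i]),
                "recall": float(rec[i]),
                "f1": float(f1[i]),
                "support": int(support[i]),
            }
            for i in range(n_classes)
        )
        return cls(
            confusion=cm,
            accuracy=float(tp.sum() / cm.sum()),
            precision=float(prec.mean()),
            recall=float(rec.mean()),
            f1=float(f1.mean()),
            per_class=per_class,
        )

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "confusion": self.confusion.tolist(),
            "per_class": list(self.per_class),
        }


def format_pm(mean: float, sd: float) -> str:
    """Render a fraction pair in the conventional 'xx.xx% ± y.yy%' style."""
    return f"{100 * mean:.2f}% ± {100 * sd:.2f}%"


def evaluate(model: CRNN, data: SampleSet, batch_size: int = 8) -> MetricsReport:
    """Score a model on a sample set."""
    preds = model.predict(data.X, batch_size=batch_size)
    return MetricsReport.from_predictions(data.y, preds, n_classes=model.config.n_classes)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _val_loss(model: CRNN, data: SampleSet, batch_size: int) -> float:
    losses, weights = [], []
    for i in range(0, len(data), batch_size):
        logits = model.forward(data.X[i : i + batch_size], training=False)
        loss, _ = cross_entropy(logits, data.y[i : i + batch_size])
        losses.append(loss)
        weights.append(len(data.y[i : i + batch_size]))
    return float(np.average(losses, weights=weights))


def train(
    model: CRNN,
    train_data: SampleSet,
    val_data: SampleSet,
    config: TrainConfig = TrainConfig(),
) -> TrainHistory:
    """Train in place; the model is left holding the best-validation weights.

    Checkpoint selection: highest validation accuracy, ties broken by lower
    validation loss.  Fully seeded: batch order comes from
    ``config.seed`` and all parameter updates are deterministic.
    """
    if len(train_data) == 0 or len(val_data) == 0:
        raise DataError("train and validation sets must be non-empty")
    leaked = set(train_data.subjects) & set(val_data.subjects)
    if leaked:
        raise DataError(f"subject leakage between train and validation sets: {sorted(leaked)}")

    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model, config)
    history = TrainHistory()
    best_state = model.get_state()
    best_acc, best_loss = -1.0, np.inf
    stale = 0
    n = len(train_data)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_losses, epoch_weights = [], []
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            loss = model.loss_and_grads(train_data.X[idx], train_data.y[idx])
            optimizer.step()
            epoch_losses.append(loss)
            epoch_weights.append(len(idx))
        history.train_loss.append(float(np.average(epoch_losses, weights=epoch_weights)))
        val_metrics = evaluate(model, val_data, config.batch_size)
        vloss = _val_loss(model, val_data, config.batch_size)
        history.val_accuracy.append(val_metrics.accuracy)
        history.val_loss.append(vloss)
        improved = val_metrics.accuracy > best_acc or (
            val_metrics.accuracy == best_acc and vloss < best_loss
        )
        if improved:
            best_acc, best_loss = val_metrics.accuracy, vloss
            best_state = model.get_state()
            history.best_epoch = epoch
            stale = 0
        else:
            stale += 1
        logger.info(
            "epoch %d: train loss %.4f, val acc %.4f, val loss %.4f%s",
            epoch,
            history.train_loss[-1],
            val_metrics.accuracy,
            vloss,
            " *" if improved else "",
        )
        if stale >= config.patience:
            break
    model.set_state(best_state)
    return history


@dataclass
class CrossValResult:
    folds: list[MetricsReport]
    histories: list[TrainHistory]

    def _stat(self, attr: str) -> tuple[float, float]:
        vals = np.array([getattr(f, attr) for f in self.folds])
        return float(vals.mean()), float(vals.std())

    def summary(self) -> dict[str, str]:
        return {
            attr: format_pm(*self._stat(attr))
            for attr in ("accuracy", "precision", "recall", "f1")
        }

    def to_dict(self) -> dict:
        means = {attr: self._stat(attr) for attr in ("accuracy", "precision", "recall", "f1")}
        return {
            "folds": [f.to_dict() for f in self.folds],
            "mean": {k: v[0] for k, v in means.items()},
            "sd": {k: v[1] for k, v in means.items()},
            "formatted": self.summary(),
        }


def cross_validate(
    data: SampleSet,
    crnn_config: CrnnConfig,
    train_config: TrainConfig = TrainConfig(),
    k: int = 10,
    seed: int = 0,
) -> CrossValResult:
    """Subject-wise k-fold cross-validation: k models, per-fold metrics.

    Folds partition the subjects so each appears in exactly one test set;
    the summary reports mean ± standard deviation across folds.
    """
    subjects = sorted(set(data.subjects))
    folds = make_cv_folds(subjects, k=k, seed=seed)
    reports, histories = [], []
    for split in folds:
        model = CRNN(crnn_config, seed=seed + split.fold_index)
        history = train(
            model,
            data.restrict(split.train_subjects),
            data.restrict(split.val_subjects),
            train_config,
        )
        reports.append(evaluate(model, data.restrict(split.test_subjects), train_config.batch_size))
        histories.append(history)
    return CrossValResult(reports, histories)
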