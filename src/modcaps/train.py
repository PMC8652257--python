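"""Training loop, margin loss, evaluation metrics, permutation importance."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix, f1_score, roc_auc_score

from .core import CapsuleConfig, CapsuleModel
from .sources import ModularDataset

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    split_ratio: float = 0.9      # train fraction of the train/validation split
    epochs: int = 50
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0
    repeats: int = 9
    m_plus: float = 0.9
    m_minus: float = 0.1
    lambda_down: float = 0.5

    def validate(self) -> None:
        problems = []
        if not 0.0 < self.split_ratio < 1.0:
            problems.append(f"split_ratio must be in (0,1), got {self.split_ratio}")
        if self.repeats < 1:
            problems.append(f"repeats must be >= 1, got {self.repeats}")
        if self.m_plus <= self.m_minus:
            problems.append(
                f"m_plus ({self.m_plus}) must exceed m_minus ({self.m_minus})"
            )
        if self.epochs < 1 or self.batch_size < 1:
            problems.append("epochs and batch_size must be >= 1")
        if problems:
            raise ValueError("; ".join(problems))


@dataclass
class EvalReport:
    """One-vs-rest AUC per class, accuracy, macro F1 and the confusion matrix."""

    class_names: list[str]
    auc: list[float | None]       # None when the class is absent from the data
    accuracy: float
    macro_f1: float
    confusion: np.ndarray

    def to_dict(self) -> dict:
        return {
            "class_names": self.class_names,
            "auc": [None if a is None else float(a) for a in self.auc],
            "accuracy": float(self.accuracy),
            "macro_f1": float(self.macro_f1),
            "confusion": self.confusion.tolist(),
        }


@dataclass
class History:
    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Margin loss
# ---------------------------------------------------------------------------

def margin_loss(
    scores: np.ndarray,
    labels: np.ndarray | int,
    cfg: TrainConfig | None = None,
    reduce: str = "mean",
) -> float:
    """CapsNet margin loss on capsule lengths.

    ``sum_j [ y_j max(0, m+ - s_j)^2 + lambda (1-y_j) max(0, s_j - m-)^2 ]``
    with y one-hot in the sample's class.
    """
    cfg = cfg or TrainConfig()
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    labels = np.atleast_1d(np.asarray(labels, dtype=np.int64))
    k = scores.shape[1]
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels must lie in [0, {k})")
    y = np.zeros_like(scores)
    y[np.arange(len(labels)), labels] = 1.0
    pos = np.maximum(0.0, cfg.m_plus - scores)
    neg = np.maximum(0.0, scores - cfg.m_minus)
    per_sample = np.sum(y * pos**2 + cfg.lambda_down * (1.0 - y) * neg**2, axis=1)
    return float(per_sample.mean() if reduce == "mean" else per_sample.sum())


def _margin_loss_grad(scores: np.ndarray, labels: np.ndarray, cfg: TrainConfig) -> np.ndarray:
    """d(mean margin loss)/d scores."""
    y = np.zeros_like(scores)
    y[np.arange(len(labels)), labels] = 1.0
    pos = np.maximum(0.0, cfg.m_plus - scores)
    neg = np.maximum(0.0, scores - cfg.m_minus)
    grad = -2.0 * y * pos + 2.0 * cfg.lambda_down * (1.0 - y) * neg
    return grad / scores.shape[0]


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

class _Adam:
    """Adaptive-moment gradient descent over a flat list of arrays."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def stratified_split(
    labels: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class shuffled split preserving class proportions within +-1 sample."""
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)  # keep both sides non-empty
        train_idx.append(idx[:n_train])
        val_idx.append(idx[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def validation_split(dataset: ModularDataset, cfg: TrainConfig) -> tuple[np.ndarray, np.ndarray]:
    """The (train, validation) index split that :func:`train` uses for ``cfg``."""
    rng = np.random.default_rng(cfg.seed)
    return stratified_split(dataset.labels, cfg.split_ratio, rng)


def train(
    dataset: ModularDataset,
    cfg: TrainConfig | None = None,
    model_config: CapsuleConfig | None = None,
) -> tuple[CapsuleModel, History]:
    """Train one capsule model on a labeled modular dataset.

    The data are split into train/validation parts, stratified by class, and
    the model is fit by mini-batch Adam on the margin loss through the full
    forward pass (encoders, prediction map and unrolled routing).
    """
    cfg = cfg or TrainConfig()
    cfg.validate()
    if dataset.labels is None:
        raise ValueError("dataset has no labels")
    classes, counts = np.unique(dataset.labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training needs at least 2 classes")
    for cls, cnt in zip(classes, counts):
        if cnt < 2:
            name = dataset.class_names[cls] if dataset.class_names else str(cls)
            raise ValueError(f"class {name!r} has {cnt} sample(s); need >= 2")

    rng = np.random.default_rng(cfg.seed)
    train_idx, val_idx = stratified_split(dataset.labels, cfg.split_ratio, rng)
    ds_train, ds_val = dataset.subset(train_idx), dataset.subset(val_idx)

    model = CapsuleModel.initialize(
        dataset.sources, dataset.class_names, config=model_config, seed=rng
    )
    opt = _Adam(model.Wp + [model.W], lr=cfg.learning_rate)

    n = ds_train.n_samples
    history = History()
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            xb = [b[batch] for b in ds_train.blocks]
            yb = ds_train.labels[batch]
            scores, _, cache = model.forward(xb, return_cache=True)
            loss = margin_loss(scores, yb, cfg)
            dscores = _margin_loss_grad(scores, yb, cfg)
            dWp, dW = model.backward(cache, dscores)
            opt.step(dWp + [dW])
            epoch_loss += loss * len(batch)
        val_acc = float(np.mean(model.predict(ds_val) == ds_val.labels))
        history.epoch.append(epoch)
        history.train_loss.append(epoch_loss / n)
        history.val_accuracy.append(val_acc)
        logger.debug("epoch %d: loss %.4f, val acc %.3f", epoch,
                     history.train_loss[-1], val_acc)
    return model, history


def train_repeats(
    dataset: ModularDataset,
    cfg: TrainConfig | None = None,
    model_config: CapsuleConfig | None = None,
) -> list[tuple[CapsuleModel, History]]:
    """Train ``cfg.repeats`` models with seeds ``cfg.seed + 0 .. cfg.seed + repeats-1``."""
    cfg = cfg or TrainConfig()
    cfg.validate()
    runs = []
    for i in range(cfg.repeats):
        rep_cfg = TrainConfig(**{**asdict(cfg), "seed": cfg.seed + i})
        runs.append(train(dataset, rep_cfg, model_config=model_config))
    return runs


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate(model: CapsuleModel, dataset: ModularDataset) -> EvalReport:
    """One-vs-rest AUC per class from capsule lengths, accuracy and macro F1.

    Classes absent from the evaluation set get AUC ``None`` and are excluded
    from the macro averages.
    """
    if dataset.labels is None:
        raise ValueError("dataset has no labels")
    model.check_dataset(dataset)
    scores = model.predict_scores(dataset)
    return evaluate_scores(scores, dataset.labels, dataset.class_names)


def evaluate_scores(
    scores: np.ndarray, labels: np.ndarray, class_names: Sequence[str]
) -> EvalReport:
    """Metric computation decoupled from the model (any per-class scorer)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    k = scores.shape[1]
    pred = np.argmax(scores, axis=1)
    present = np.unique(labels)
    auc: list[float | None] = []
    for j in range(k):
        y = (labels == j).astype(int)
        if j not in present or y.all():
            auc.append(None)
            continue
        if np.ptp(scores[:, j]) == 0:
            auc.append(0.5)  # uninformative scorer convention
        else:
            auc.append(float(roc_auc_score(y, scores[:, j])))
    accuracy = float(np.mean(pred == labels))
    macro_f1 = float(
        f1_score(labels, pred, labels=present, average="macro", zero_division=0)
    )
    confusion = confusion_matrix(labels, pred, labels=np.arange(k))
    names = list(class_names) if class_names else [str(j) for j in range(k)]
    return EvalReport(class_names=names, auc=auc, accuracy=accuracy,
                      macro_f1=macro_f1, confusion=confusion)


# ---------------------------------------------------------------------------
# Permutation importance baseline
# ---------------------------------------------------------------------------

def _mean_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    report = evaluate_scores(scores, labels, [])
    vals = [a for a in report.auc if a is not None]
    return float(np.mean(vals))

def permutation_importance(
    scorer: Callable[[list[np.ndarray]], np.ndarray],
    dataset: ModularDataset,
    seed: int = 0,
    n_repeats: int = 5,
) -> list[np.ndarray]:
    """Per-feature mean-AUC drop under column shuffling.

    ``scorer`` maps a list of source blocks to an (n_samples, k) score
    matrix; any fitted model exposing that contract works (the capsule model
    does via ``model.predict_scores``). Returns one importance vector per
    source, aligned with the source's features. Shuffling a constant column
    leaves scores untouched, so its importance is exactly 0.
    """
    if dataset.labels is None:
        raise ValueError("dataset has no labels")
    scorer_fn = scorer.predict_scores if isinstance(scorer, CapsuleModel) else scorer
    rng = np.random.default_rng(seed)
    baseline = _mean_auc(np.asarray(scorer_fn(dataset.blocks)), dataset.labels)
    out: list[np.ndarray] = []
    for i, block in enumerate(dataset.blocks):
        drops = np.zeros(block.shape[1])
        for jcol in range(block.shape[1]):
            col = block[:, jcol]
            if np.ptp(col) == 0:
                drops[jcol] = 0.0  # permutation of a constant is the identity
                continue
            acc = 0.0
            for _ in range(n_repeats):
                perm = rng.permutation(len(col))
                shuffled = [b if ii != i else b.copy() for ii, b in enumerate(dataset.blocks)]
                shuffled[i][:, jcol] = col[perm]
                acc += baseline - _mean_auc(np.asarray(scorer_fn(shuffled)), dataset.labels)
            drops[jcol] = acc / n_repeats
        out.append(drops)
    return out


def grouped_importance(per_feature: list[np.ndarray]) -> np.ndarray:
    """Sum per-feature importance scores within each source group."""
    return np.array([float(np.sum(v)) for v in per_feature])


def importance_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two per-source importance vectors."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("importance vectors must be 1-D, equal length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("undefined correlation: constant importance vector")
    ac, bc = a - a.mean(), b - b.mean()
    return float(np.sum(ac * bc) / np.sqrt(np.sum(ac * ac) * np.sum(bc * bc)))
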