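"""Model training, cross-validation, grid search and evaluation metrics.

Training minimizes categorical cross-entropy on the two-way softmax with
Adam.  Model selection follows stratified five-fold cross-validation with
the Matthews correlation coefficient (MCC) as the primary criterion: MCC
is the most stringent of the confusion-matrix scores for balanced binary
problems, penalizing errors in either class.

Metrics are the field-standard set: ACC, Sen (recall on ACPs), Spc
(recall on non-ACPs) as percentages, MCC in [-1, 1], and ROC-AUC (the
Mann-Whitney concordance probability).
"""

from __future__ import annotations

import itertools
import logging
import math
import time
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .autodiff import Adam, Tensor, cross_entropy
from .encoders import StandardizedTable, default_standardized_table, encode_dataset
from .network import ModelConfig, TrainedModel, _forward_core, build_model
from .sequence_io import PeptideDataset, SplitSpec, stratified_kfold

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsRecord:
    acc: float          # percent
    sen: float          # percent
    spc: float          # percent
    mcc: float
    auc: float | None = None

    def as_dict(self) -> dict:
        return {
            "acc": self.acc, "sen": self.sen, "spc": self.spc,
            "mcc": self.mcc, "auc": self.auc,
        }


def confusion(
    predictions: np.ndarray, labels: Sequence[int], threshold: float = 0.5
) -> ConfusionMatrix:
    """Confusion counts; a peptide is called ACP iff P(ACP) >= threshold.

    `predictions` may be (N, 2) probability pairs or an N-vector of P(ACP).
    """
    predictions = np.asarray(predictions, dtype=float)
    scores = predictions[:, 1] if predictions.ndim == 2 else predictions
    labels = np.asarray(labels, dtype=int)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError(
            f"length mismatch: {scores.shape[0]} predictions, {labels.shape[0]} labels"
        )
    calls = scores >= threshold
    pos = labels == 1
    return ConfusionMatrix(
        TP=int(np.sum(calls & pos)),
        TN=int(np.sum(~calls & ~pos)),
        FP=int(np.sum(calls & ~pos)),
        FN=int(np.sum(~calls & pos)),
    )


def metrics(cm: ConfusionMatrix, auc: float | None = None) -> MetricsRecord:
    """ACC/Sen/Spc as percentages and MCC from confusion counts.

    Convention: any ratio with a zero denominator (including the MCC
    denominator) is reported as 0, so degenerate folds cannot poison a
    grid search with NaNs.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, tn, fp, fn = cm.TP, cm.TN, cm.FP, cm.FN
    acc = 100.0 * (tp + tn) / cm.total
    sen = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    spc = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return MetricsRecord(acc=acc, sen=sen, spc=spc, mcc=mcc, auc=auc)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve == Mann-Whitney pair statistic.

    Equals (concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg); the
    test suite checks this against exhaustive pair enumeration.
    """
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("roc_auc requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def evaluate_predictions(
    predictions: np.ndarray, labels: Sequence[int], threshold: float = 0.5
) -> MetricsRecord:
    """Full metric record (including AUC) for probability predictions."""
    cm = confusion(predictions, labels, threshold=threshold)
    predictions = np.asarray(predictions, dtype=float)
    scores = predictions[:, 1] if predictions.ndim == 2 else predictions
    return metrics(cm, auc=roc_auc(scores, labels))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _model_inputs(
    dataset: PeptideDataset, config: ModelConfig, std: StandardizedTable
) -> np.ndarray:
    return encode_dataset(dataset, config.input_scheme, std, lmax=config.lmax)


def train(
    config: ModelConfig,
    train_data: PeptideDataset,
    std: StandardizedTable | None = None,
) -> TrainedModel:
    """Train a model for exactly `config.epochs` epochs of Adam updates.

    Deterministic given `config.seed`: parameter initialization and the
    per-epoch shuffles derive from it.  Per-epoch mean loss is recorded in
    the returned model's training log.
    """
    y = train_data.labels
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    std = std or default_standardized_table()
    model = build_model(config)
    model.standardization = std
    X = _model_inputs(train_data, config, std)
    lengths = np.array([len(p) for p in train_data])
    opt = Adam(list(model.params.values()), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    n = X.shape[0]
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        t0 = time.perf_counter()
        for lo in range(0, n, config.batch_size):
            idx = order[lo: lo + config.batch_size]
            logits, _ = _forward_core(
                model.params, config, Tensor(X[idx]),
                lengths=lengths[idx] if config.mask_padding else None,
            )
            loss = cross_entropy(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        mean_loss = float(np.mean(losses))
        model.training_log.append(
            {"epoch": epoch + 1, "loss": mean_loss,
             "seconds": round(time.perf_counter() - t0, 3)}
        )
        logger.debug("epoch %d/%d loss %.4f", epoch + 1, config.epochs, mean_loss)
    return model


# ---------------------------------------------------------------------------
# Cross-validation and grid search
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    fold_metrics: list[MetricsRecord]
    mean: MetricsRecord
    config: ModelConfig
    split: SplitSpec


def _mean_record(records: Sequence[MetricsRecord]) -> MetricsRecord:
    aucs = [r.auc for r in records]
    return MetricsRecord(
        acc=float(np.mean([r.acc for r in records])),
        sen=float(np.mean([r.sen for r in records])),
        spc=float(np.mean([r.spc for r in records])),
        mcc=float(np.mean([r.mcc for r in records])),
        auc=None if any(a is None for a in aucs) else float(np.mean(aucs)),
    )


def cross_validate(
    config: ModelConfig,
    data: PeptideDataset,
    K: int = 5,
    seed: int = 0,
    std: StandardizedTable | None = None,
) -> CVResult:
    """Stratified K-fold CV; per-fold metrics averaged arithmetically.

    Each fold's model is retrained from scratch with a fold-derived seed
    (config.seed + fold index), and AUC is averaged per fold rather than
    pooled across folds.
    """
    split = stratified_kfold(data, K=K, seed=seed)
    std = std or default_standardized_table()
    fold_metrics = []
    for k in range(K):
        val_ids = set(split.fold_ids(k))
        tr = data.subset([i for i in data.ids if i not in val_ids])
        va = data.subset(val_ids)
        model = train(replace(config, seed=config.seed + k), tr, std=std)
        probs = model.forward(_model_inputs(va, config, std))
        fold_metrics.append(evaluate_predictions(probs, va.labels))
        logger.info("fold %d/%d: %s", k + 1, K, fold_metrics[-1])
    return CVResult(
        fold_metrics=fold_metrics,
        mean=_mean_record(fold_metrics),
        config=config,
        split=split,
    )


@dataclass
class GridResult:
    results: list[CVResult]
    best: CVResult


def make_grid(base: ModelConfig, **axes: Iterable) -> list[ModelConfig]:
    """Cartesian product of config field values over `base`."""
    names = list(axes)
    configs = []
    for combo in itertools.product(*(list(axes[n]) for n in names)):
        configs.append(replace(base, **dict(zip(names, combo))))
    return configs


def grid_search(
    grid: Sequence[ModelConfig],
    data: PeptideDataset,
    K: int = 5,
    seed: int = 0,
    std: StandardizedTable | None = None,
) -> GridResult:
    """Evaluate every config by K-fold CV; pick the best mean MCC.

    Ties break by higher mean ACC, then fewer epochs (smaller model
    preferred), then grid order.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty grid")
    results = [cross_validate(c, data, K=K, seed=seed, std=std) for c in grid]
    best = max(
        range(len(results)),
        key=lambda i: (
            results[i].mean.mcc,
            results[i].mean.acc,
            -results[i].config.epochs,
            -i,
        ),
    )
    return GridResult(results=results, best=results[best])
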