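"""Focal-loss training, evaluation metrics, and patient-grouped protocols.

Cross-validation is grouped at the patient level: grouped stratified k-fold
(patients ordered by descending spasm count, dealt round-robin) and
leave-one-patient-out.  No epoch from a held-out patient ever enters a
training batch; this is audited at batch-assembly time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .autodiff import Adam, Tensor
from .errors import ValidationError
from .io import EpochSet
from .model import CrossModalGraphClassifier, ModelConfig, RegionMap


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    batch_size: int = 32
    epochs: int = 150
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    seed: int = 0
    decision_threshold: float = 0.5

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if not 0 < self.focal_alpha < 1:
            raise ValidationError("focal_alpha must lie in (0, 1)")
        if self.focal_gamma < 0:
            raise ValidationError("focal_gamma must be non-negative")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")


@dataclass
class FoldSplit:
    folds: list[tuple[list[str], list[str]]]  # (train_patients, test_patients)

    def __post_init__(self):
        all_test: list[str] = []
        for train, test in self.folds:
            if set(train) & set(test):
                raise ValidationError("train and test patients overlap in a fold")
            all_test.extend(test)
        if len(all_test) != len(set(all_test)):
            raise ValidationError("a patient appears in more than one test fold")

    @property
    def n_folds(self) -> int:
        return len(self.folds)


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    auc: float | None = None
    degenerate: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "specificity": self.specificity,
            "f1": self.f1, "auc": self.auc,
        }


# ---------------------------------------------------------------------------
# loss and metrics
# ---------------------------------------------------------------------------

def focal_loss(p_hat, y, alpha: float = 0.25, gamma: float = 2.0) -> float:
    """Mean focal loss: ``-alpha_t * (1 - p_t)^gamma * log(p_t)`` with
    ``p_t = p`` for positives and ``1 - p`` for negatives."""
    p = np.clip(np.asarray(p_hat, dtype=np.float64), 1e-7, 1.0 - 1e-7)
    y = np.asarray(y, dtype=np.float64)
    p_t = np.where(y == 1, p, 1.0 - p)
    alpha_t = np.where(y == 1, alpha, 1.0 - alpha)
    return float(np.mean(-alpha_t * (1.0 - p_t) ** gamma * np.log(p_t)))


def focal_loss_on_logits(logits: Tensor, y: np.ndarray, alpha: float,
                         gamma: float) -> Tensor:
    """Differentiable focal loss used by the training loop.

    Probabilities are squeezed into [1e-7, 1 - 1e-7] by an affine map, the
    smooth analogue of the clamping used in :func:`focal_loss`.
    """
    y = np.asarray(y, dtype=logits.data.dtype)
    p = logits.sigmoid() * (1.0 - 2e-7) + 1e-7
    p_t = p * y + (1.0 - p) * (1.0 - y)
    alpha_t = alpha * y + (1.0 - alpha) * (1.0 - y)
    losses = (p_t * (-1.0) + 1.0) ** gamma * p_t.log() * alpha_t * (-1.0)
    return losses.mean()


def confusion_metrics(labels, predictions) -> MetricsReport:
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValidationError(
            f"{labels.shape[0]} labels vs {predictions.shape[0]} predictions"
        )
    if labels.size and (not np.isin(labels, (0, 1)).all()
                        or not np.isin(predictions, (0, 1)).all()):
        raise ValidationError("labels and predictions must be binary")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    degenerate = []

    def ratio(num, den, name):
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    specificity = ratio(tn, tn + fp, "specificity")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    accuracy = ratio(tp + tn, tp + tn + fp + fn, "accuracy")
    return MetricsReport(
        tp=tp, tn=tn, fp=fp, fn=fn, accuracy=accuracy, precision=precision,
        recall=recall, specificity=specificity, f1=f1, degenerate=degenerate,
    )


def auc_rank(scores, labels) -> float:
    """Rank-sum AUC with average ranks for ties:
    ``(sum of positive ranks - P(P+1)/2) / (P * N)``."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC undefined without both classes present")
    ranks = rankdata(scores, method="average")
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def _spasm_count(value) -> float:
    if isinstance(value, (tuple, list)):
        return float(value[0])
    return float(value)


def grouped_stratified_kfold(patients: dict, k: int = 5,
                             seed: int | None = None) -> FoldSplit:
    """Deal patients (ordered by descending spasm count, ties by id) into
    ``k`` folds round-robin; fold ``i`` is test, the rest train.

    ``seed`` is accepted for interface stability; the dealing itself is
    deterministic.
    """
    if k > len(patients):
        raise ValidationError(f"cannot make {k} folds from {len(patients)} patients")
    if k < 2:
        raise ValidationError("need at least 2 folds")
    ordered = sorted(patients, key=lambda pid: (-_spasm_count(patients[pid]), pid))
    buckets: list[list[str]] = [[] for _ in range(k)]
    for position, pid in enumerate(ordered):
        buckets[position % k].append(pid)
    folds = []
    for i in range(k):
        test = list(buckets[i])
        train = [pid for j, bucket in enumerate(buckets) if j != i for pid in bucket]
        folds.append((train, test))
    return FoldSplit(folds=folds)


def leave_one_patient_out(patients) -> FoldSplit:
    ids = sorted(patients)
    if len(ids) < 2:
        raise ValidationError("leave-one-patient-out requires >= 2 patients")
    folds = [([p for p in ids if p != held_out], [held_out]) for held_out in ids]
    return FoldSplit(folds=folds)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    report: MetricsReport
    checkpoint: dict[str, np.ndarray]
    loss_curve: list[float]
    test_index: np.ndarray
    test_probabilities: np.ndarray


@dataclass
class TrainResult:
    folds: list[FoldResult]

    def reports_frame(self) -> pd.DataFrame:
        rows = [f.report.to_row() for f in self.folds]
        return pd.DataFrame(rows).assign(fold=range(len(rows)))


def _stack_graphs(graph_list):
    weights = np.stack([g.weights for g in graph_list]).astype(np.float32)
    feats = np.stack([g.node_features for g in graph_list]).astype(np.float32)
    return feats, weights


def train(es: EpochSet, graphs, split: FoldSplit, cfg: TrainConfig | None = None,
          model_cfg: ModelConfig | None = None,
          region_map: RegionMap | None = None,
          eval_batch_size: int = 64) -> TrainResult:
    """Train one model per fold and evaluate it on the fold's held-out
    patients.  ``graphs`` is the ``(temporal, spectral)`` pair returned by
    :func:`eeggnn.graphs.build_graphs`."""
    cfg = cfg or TrainConfig()
    model_cfg = model_cfg or ModelConfig()
    temporal, spectral = graphs
    if temporal is None or spectral is None:
        raise ValidationError("training requires both graph modalities")
    if len(temporal) != es.n_epochs or len(spectral) != es.n_epochs:
        raise ValidationError("graph count does not match epoch count")

    xt = np.asarray(es.epochs, dtype=np.float32)
    _, wt = _stack_graphs(temporal)
    xs, ws = _stack_graphs(spectral)
    labels = np.asarray(es.labels)
    patient_arr = np.asarray(es.patient_ids)

    results = []
    for fold_index, (train_pats, test_pats) in enumerate(split.folds):
        train_idx = np.flatnonzero(np.isin(patient_arr, list(train_pats)))
        test_idx = np.flatnonzero(np.isin(patient_arr, list(test_pats)))
        if train_idx.size == 0:
            raise ValidationError(f"fold {fold_index}: empty training fold")
        # leakage audit: no test patient may contribute a training epoch
        if set(patient_arr[train_idx]) & set(test_pats):
            raise ValidationError(f"fold {fold_index}: patient leakage detected")

        model = CrossModalGraphClassifier(
            model_cfg, region_map=region_map,
            channel_names=list(es.channel_names), seed=cfg.seed,
        )
        optimizer = Adam(model.params, lr=cfg.learning_rate)
        rng = np.random.default_rng((cfg.seed, fold_index))
        curve = []
        for _ in range(cfg.epochs):
            order = rng.permutation(train_idx)
            epoch_losses = []
            for start in range(0, order.size, cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                optimizer.zero_grad()
                logits = model.forward_batch(
                    xt[batch], wt[batch], xs[batch], ws[batch],
                    training=True, rng=rng,
                )
                loss = focal_loss_on_logits(
                    logits, labels[batch], cfg.focal_alpha, cfg.focal_gamma
                )
                loss.backward()
                optimizer.step()
                epoch_losses.append(float(loss.data))
            curve.append(float(np.mean(epoch_losses)))

        probs = predict_in_batches(model, xt, wt, xs, ws, test_idx,
                                   batch_size=eval_batch_size)
        report = evaluate_probabilities(labels[test_idx], probs,
                                        threshold=cfg.decision_threshold)
        results.append(FoldResult(
            report=report,
            checkpoint=model.state_dict(),
            loss_curve=curve,
            test_index=test_idx,
            test_probabilities=probs,
        ))
    return TrainResult(folds=results)


def predict_in_batches(model: CrossModalGraphClassifier, xt, wt, xs, ws,
                       index, batch_size: int = 64) -> np.ndarray:
    index = np.asarray(index)
    probs = np.empty(index.size, dtype=np.float64)
    for start in range(0, index.size, batch_size):
        sel = index[start : start + batch_size]
        probs[start : start + sel.size] = model.predict_proba(
            xt[sel], wt[sel], xs[sel], ws[sel]
        )
    return probs


def evaluate_probabilities(labels, probs, threshold: float = 0.5) -> MetricsReport:
    labels = np.asarray(labels)
    predictions = (np.asarray(probs) >= threshold).astype(int)
    report = confusion_metrics(labels, predictions)
    if len(set(labels.tolist())) == 2:
        report.auc = auc_rank(probs, labels)
    return report
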