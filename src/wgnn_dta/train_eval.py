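"""Training loops, cross-validation splits, and the metric suite.

Regression (DTA) is scored with mean squared error, concordance index
and the Pearson correlation coefficient; classification (CPI) with
ROC-AUC, precision, recall and F1.  The concordance index follows the
standard Harrell pairwise definition: over all pairs whose true labels
are strictly ordered, a concordant prediction scores 1, a tied
prediction 0.5, a discordant one 0.

Training uses Adam on the task loss (mean squared error for DTA, binary
cross-entropy on logits for CPI).  Reference hyperparameters are
lr 0.001, batch 512, 1000 epochs (CPI) or 2000 epochs (DTA); runs in
this package's tests scale epochs down and are fully seeded (data
order, parameter init, dropout).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from ._autograd import Adam, Tensor
from .datasets_io import PairDataset
from .mol_graph import build_molecular_graph
from .protein_graph import build_weighted_protein_graph
from .wgnn_model import GraphBatch, ModelConfig, WgnnModel, prepare_batch

__all__ = [
    "Metrics",
    "TrainConfig",
    "precision",
    "recall",
    "f1",
    "concordance_index",
    "pkd_transform",
    "mse",
    "pearson",
    "auc",
    "make_folds",
    "subsample_negatives",
    "train",
    "evaluate",
    "predict_dataset",
]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def precision(tp: int, fp: int) -> float:
    """TP / (TP + FP); NaN (flagged undefined) when no positive calls."""
    if tp + fp == 0:
        warnings.warn("precision undefined: no positive predictions")
        return math.nan
    return tp / (tp + fp)


def recall(tp: int, fn: int) -> float:
    """TP / (TP + FN); NaN when there are no actual positives."""
    if tp + fn == 0:
        warnings.warn("recall undefined: no actual positives")
        return math.nan
    return tp / (tp + fn)


def f1(p: float, r: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 by convention when both are 0."""
    if p == 0 and r == 0:
        return 0.0
    return 2 * p * r / (p + r)


def concordance_index(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    """Harrell concordance index with 0.5 credit for prediction ties."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D and equal length")
    # pairwise differences over strictly ordered true pairs
    dt = yt[:, None] - yt[None, :]
    dp = yp[:, None] - yp[None, :]
    ordered = dt > 0
    n_pairs = int(ordered.sum())
    if n_pairs == 0:
        warnings.warn("concordance index undefined: no ordered pairs")
        return math.nan
    credit = np.where(dp > 0, 1.0, np.where(dp == 0, 0.5, 0.0))
    return float(credit[ordered].sum() / n_pairs)


def pkd_transform(kd_nm: float) -> float:
    """pKd = -log10(Kd / 1e9) for a dissociation constant in nM."""
    if kd_nm <= 0:
        raise ValueError(f"Kd must be positive, got {kd_nm}")
    return -math.log10(kd_nm / 1e9)


def mse(y_true, y_pred) -> float:
    yt, yp = np.asarray(y_true, float), np.asarray(y_pred, float)
    return float(np.mean((yt - yp) ** 2))


def pearson(y_true, y_pred) -> float:
    return float(stats.pearsonr(np.asarray(y_true), np.asarray(y_pred))[0])


def auc(y_true, scores) -> float:
    """ROC-AUC by rank statistic over the scores."""
    return float(roc_auc_score(np.asarray(y_true), np.asarray(scores)))


@dataclass(frozen=True)
class Metrics:
    """Evaluation summary; regression fields are None for CPI and vice
    versa.  Undefined values (e.g. precision with no positive calls)
    are NaN."""

    mse: float | None = None
    ci: float | None = None
    pearson: float | None = None
    auc: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {
            k: v for k, v in self.__dict__.items() if v is not None
        }


def regression_metrics(y_true, y_pred) -> Metrics:
    return Metrics(
        mse=mse(y_true, y_pred),
        ci=concordance_index(y_true, y_pred),
        pearson=pearson(y_true, y_pred),
    )


def classification_metrics(y_true, scores, threshold: float = 0.5) -> Metrics:
    yt = np.asarray(y_true, float)
    calls = np.asarray(scores, float) > threshold
    tp = int(np.sum(calls & (yt == 1)))
    fp = int(np.sum(calls & (yt == 0)))
    fn = int(np.sum(~calls & (yt == 1)))
    p, r = precision(tp, fp), recall(tp, fn)
    return Metrics(
        auc=auc(yt, scores),
        precision=p,
        recall=r,
        f1=f1(p, r) if not (math.isnan(p) or math.isnan(r)) else math.nan,
    )


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def make_folds(n: int | PairDataset, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Random partition into k folds of near-equal size (|size diff| <= 1),
    deterministic per seed."""
    size = n if isinstance(n, int) else len(n)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if size < k:
        raise ValueError(f"cannot split {size} records into {k} folds")
    perm = np.random.default_rng(seed).permutation(size)
    return [np.sort(part) for part in np.array_split(perm, k)]


def subsample_negatives(
    dataset: PairDataset, neg_per_pos: float, seed: int = 0
) -> PairDataset:
    """Keep all positives and sample negatives without replacement to
    ``neg_per_pos`` negatives per positive (a 1:r positive:negative
    ratio), clamped to availability with a warning."""
    labels = dataset.labels
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("subsample_negatives needs both classes present")
    want = int(round(neg_per_pos * pos.size))
    if want > neg.size:
        warnings.warn(
            f"requested {want} negatives but only {neg.size} available; "
            "keeping all"
        )
        want = neg.size
    rng = np.random.default_rng(seed)
    keep_neg = rng.choice(neg, size=want, replace=False)
    keep = np.sort(np.concatenate([pos, keep_neg]))
    return dataset.subset(keep)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimization hyperparameters.  The reference settings are
    lr 0.001, batch 512, 1000 (CPI) / 2000 (DTA) epochs; pass smaller
    ``epochs`` (and typically a larger ``learning_rate``) for desk-scale
    runs."""

    learning_rate: float = 1e-3
    batch_size: int = 512
    epochs: int = 2000
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")


class _GraphCache:
    """Featurized graphs for the distinct molecules and proteins of a
    dataset; each distinct graph is built once and encoded once per
    batch it appears in."""

    def __init__(self, dataset: PairDataset):
        self.mol_graphs = {}
        self.prot_graphs = {}
        for rec in dataset.records:
            if rec.mol_id not in self.mol_graphs:
                self.mol_graphs[rec.mol_id] = build_molecular_graph(rec.smiles)
        for pid in {r.prot_id for r in dataset.records}:
            self.prot_graphs[pid] = build_weighted_protein_graph(
                dataset.sequences[pid], dataset.contact_maps[pid]
            )

    def batch_for(
        self, dataset: PairDataset, indices: np.ndarray, use_edge_weights: bool
    ) -> tuple[GraphBatch, GraphBatch, np.ndarray, np.ndarray, np.ndarray]:
        recs = [dataset.records[i] for i in indices]
        mol_ids = sorted({r.mol_id for r in recs})
        prot_ids = sorted({r.prot_id for r in recs})
        mol_pos = {m: i for i, m in enumerate(mol_ids)}
        prot_pos = {p: i for i, p in enumerate(prot_ids)}
        mol_batch = prepare_batch(
            [self.mol_graphs[m] for m in mol_ids], use_edge_weights=True
        )
        prot_batch = prepare_batch(
            [self.prot_graphs[p] for p in prot_ids],
            use_edge_weights=use_edge_weights,
        )
        return (
            mol_batch,
            prot_batch,
            np.array([mol_pos[r.mol_id] for r in recs]),
            np.array([prot_pos[r.prot_id] for r in recs]),
            np.array([r.label for r in recs]),
        )


def _loss(pred: Tensor, y: np.ndarray, task: str) -> Tensor:
    if task == "dta":
        diff = pred - Tensor(y)
        return (diff * diff).mean()
    # stable binary cross-entropy on logits: softplus(z) - y*z
    return (pred.softplus() - pred * Tensor(y)).mean()


def train(
    dataset: PairDataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
    model: WgnnModel | None = None,
) -> tuple[WgnnModel, list[float]]:
    """Train a model on a pair dataset; returns the model and the
    per-epoch mean loss log.  Fully deterministic for a fixed seed
    (parameter init, shuffling and dropout all derive from it)."""
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    if dataset.task != model_config.task:
        raise ValueError(
            f"dataset task {dataset.task!r} does not match model task "
            f"{model_config.task!r}"
        )
    labels = dataset.labels
    if model_config.task == "cpi" and not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("CPI training requires binary labels")

    seed = train_config.seed
    if model is None:
        model = WgnnModel(model_config, seed=seed)
    cache = _GraphCache(dataset)
    opt = Adam(model.parameters(), lr=train_config.learning_rate)
    shuffle_rng = np.random.default_rng(seed + 1)
    dropout_rng = np.random.default_rng(seed + 2)

    n = len(dataset)
    bs = train_config.batch_size
    # batch composition is constant when everything fits in one batch,
    # so the packed graphs can be reused across epochs
    single_batch = (
        cache.batch_for(dataset, np.arange(n), model_config.use_edge_weights)
        if bs >= n
        else None
    )
    history: list[float] = []
    for _ in range(train_config.epochs):
        if single_batch is not None:
            batches = [single_batch]
        else:
            order = shuffle_rng.permutation(n)
            batches = [
                cache.batch_for(
                    dataset, order[s : s + bs], model_config.use_edge_weights
                )
                for s in range(0, n, bs)
            ]
        epoch_loss = 0.0
        for mol_b, prot_b, mol_pos, prot_pos, y in batches:
            opt.zero_grad()
            pred = model.forward_logits(
                mol_b, prot_b, mol_pos, prot_pos,
                training=True, dropout_rng=dropout_rng,
            )
            loss = _loss(pred, y, model_config.task)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(y)
        history.append(epoch_loss / n)
    return model, history


def predict_dataset(
    model: WgnnModel, dataset: PairDataset, indices=None
) -> np.ndarray:
    """Evaluation-mode predictions for (a subset of) a dataset, in row
    order (CPI: probabilities; DTA: affinities)."""
    if indices is None:
        indices = np.arange(len(dataset))
    indices = np.asarray(indices, dtype=int)
    cache = _GraphCache(dataset)
    mol_b, prot_b, mol_pos, prot_pos, _ = cache.batch_for(
        dataset, indices, model.config.use_edge_weights
    )
    out = model.forward_logits(mol_b, prot_b, mol_pos, prot_pos).data
    if model.config.task == "cpi":
        out = 1.0 / (1.0 + np.exp(-out))
    return out


def evaluate(model: WgnnModel, dataset: PairDataset, indices=None) -> Metrics:
    """Score a trained model on (a subset of) a dataset with the metric
    suite of its task."""
    if indices is None:
        indices = np.arange(len(dataset))
    indices = np.asarray(indices, dtype=int)
    preds = predict_dataset(model, dataset, indices)
    y = dataset.labels[indices]
    if model.config.task == "dta":
        return regression_metrics(y, preds)
    return classification_metrics(y, preds)
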