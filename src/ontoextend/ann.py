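"""Single-hidden-layer neural network classifier and its evaluation.

The network is input -> sigmoid hidden layer -> softmax output, trained with
full-batch Adam on the cross-entropy loss.  The binary task is handled as a
2-way softmax, so the output layer always has one unit per label.
Evaluation reports per-label precision/recall/F-score and one-vs-rest
ROC/AUC with macro averages, plus the confusion matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    auc,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold

from .datasets import LabeledDataset, SplitConfig, split as split_dataset

HIDDEN_SIZE_GRID = (10, 50, 100, 200)


@dataclass
class ANNConfig:
    """Architecture and optimization settings.

    The hidden layer uses a sigmoid activation; 200 units is the default
    size (the best-performing point of the 10/50/100/200 grid).
    """

    hidden_size: int = 200
    max_epochs: int = 300
    learning_rate: float = 0.01
    seed: int = 0
    hidden_activation: str = "sigmoid"

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.hidden_activation != "sigmoid":
            raise ValueError("only sigmoid hidden activation is supported")


@dataclass
class ANNModel:
    """Learned weights of the two-layer network plus its label names."""

    w1: np.ndarray  # (input_dim, hidden)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden, n_labels)
    b2: np.ndarray  # (n_labels,)
    label_names: list[str]

    @property
    def input_dim(self) -> int:
        return self.w1.shape[0]

    @property
    def hidden_size(self) -> int:
        return self.w1.shape[1]

    @property
    def n_labels(self) -> int:
        return self.w2.shape[1]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        h = _sigmoid(np.asarray(X) @ self.w1 + self.b1)
        return _softmax(h @ self.w2 + self.b2)

    def predict(self, X: np.ndarray) -> list[str]:
        p = self.predict_proba(X)
        return [self.label_names[i] for i in p.argmax(axis=1)]

    def save(self, path: str | Path) -> None:
        payload = {
            "label_names": self.label_names,
            "w1": self.w1.tolist(), "b1": self.b1.tolist(),
            "w2": self.w2.tolist(), "b2": self.b2.tolist(),
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "ANNModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(w1=np.array(d["w1"]), b1=np.array(d["b1"]),
                   w2=np.array(d["w2"]), b2=np.array(d["b2"]),
                   label_names=list(d["label_names"]))


@dataclass
class EvalReport:
    """Per-label and macro metrics on a labeled evaluation set."""

    label_names: list[str]
    precision: dict[str, float]
    recall: dict[str, float]
    f_score: dict[str, float]
    auc_per_label: dict[str, float]
    macro_f: float
    macro_auc: float
    confusion: np.ndarray
    roc_points: dict[str, list[tuple[float, float]]]
    support: dict[str, int] = field(default_factory=dict)

    @property
    def positive_f(self) -> float:
        """Binary convenience: F of the first label."""
        return self.f_score[self.label_names[0]]

    @property
    def positive_auc(self) -> float:
        return self.auc_per_label[self.label_names[0]]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("label\tprecision\trecall\tf_score\tauc\tsupport\n")
            for lab in self.label_names:
                fh.write(f"{lab}\t{self.precision[lab]:.6f}\t"
                         f"{self.recall[lab]:.6f}\t{self.f_score[lab]:.6f}\t"
                         f"{self.auc_per_label[lab]:.6f}\t"
                         f"{self.support.get(lab, 0)}\n")
            fh.write(f"MACRO\t\t\t{self.macro_f:.6f}\t"
                     f"{self.macro_auc:.6f}\t{int(self.confusion.sum())}\n")

    def roc_to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for lab in self.label_names:
            safe = lab.replace(":", "_").replace("/", "_")
            with open(directory / f"roc_{safe}.csv", "w",
                      encoding="utf-8") as fh:
                fh.write("fpr,tpr\n")
                for fpr, tpr in self.roc_points[lab]:
                    fh.write(f"{fpr:.6f},{tpr:.6f}\n")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def train_ann(ds: LabeledDataset, cfg: ANNConfig = ANNConfig()) -> ANNModel:
    """Fit the network on a dataset's items (full-batch Adam, fixed seed).

    Raises if only one label is present — a softmax over one class cannot
    be trained discriminatively.
    """
    X = np.asarray(ds.features, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    present = [l for l in ds.label_names if l in set(ds.labels)]
    if len(present) < 2:
        raise ValueError(f"need >= 2 labels to train, got {present}")
    label_to_i = {l: i for i, l in enumerate(present)}
    y = np.array([label_to_i[l] for l in ds.labels])
    n, d = X.shape
    k = len(present)
    rng = np.random.default_rng(cfg.seed)
    w1 = rng.normal(0.0, np.sqrt(2.0 / (d + cfg.hidden_size)),
                    size=(d, cfg.hidden_size))
    b1 = np.zeros(cfg.hidden_size)
    w2 = rng.normal(0.0, np.sqrt(2.0 / (cfg.hidden_size + k)),
                    size=(cfg.hidden_size, k))
    b2 = np.zeros(k)
    Y = np.zeros((n, k))
    Y[np.arange(n), y] = 1.0

    params = [w1, b1, w2, b2]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    for t in range(1, cfg.max_epochs + 1):
        h = _sigmoid(X @ w1 + b1)
        p = _softmax(h @ w2 + b2)
        delta_out = (p - Y) / n                     # (n, k)
        g_w2 = h.T @ delta_out
        g_b2 = delta_out.sum(axis=0)
        delta_hid = (delta_out @ w2.T) * h * (1 - h)
        g_w1 = X.T @ delta_hid
        g_b1 = delta_hid.sum(axis=0)
        for p_, m_, v_, g in zip(params, m, v, [g_w1, g_b1, g_w2, g_b2]):
            m_ *= beta1
            m_ += (1 - beta1) * g
            v_ *= beta2
            v_ += (1 - beta2) * g * g
            mhat = m_ / (1 - beta1 ** t)
            vhat = v_ / (1 - beta2 ** t)
            p_ -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
    return ANNModel(w1=w1, b1=b1, w2=w2, b2=b2, label_names=present)


def evaluate(model: ANNModel, ds: LabeledDataset) -> EvalReport:
    """Per-label P/R/F and one-vs-rest ROC/AUC with macro averages.

    Labels without positive (or without negative) examples in the test set
    get AUC 0.5 by convention; this keeps macro averaging total.
    """
    if len(ds) == 0:
        raise ValueError("empty evaluation set")
    missing = set(ds.labels) - set(model.label_names)
    if missing:
        raise ValueError(f"test labels unknown to the model: {missing}")
    X = np.asarray(ds.features, dtype=np.float64)
    proba = model.predict_proba(X)
    pred = [model.label_names[i] for i in proba.argmax(axis=1)]
    names = model.label_names
    prec, rec, f1, support = precision_recall_fscore_support(
        ds.labels, pred, labels=names, zero_division=0)
    conf = confusion_matrix(ds.labels, pred, labels=names)
    aucs: dict[str, float] = {}
    rocs: dict[str, list[tuple[float, float]]] = {}
    for j, lab in enumerate(names):
        y_bin = np.array([1 if l == lab else 0 for l in ds.labels])
        if y_bin.min() == y_bin.max():
            aucs[lab] = 0.5
            rocs[lab] = [(0.0, 0.0), (1.0, 1.0)]
            continue
        fpr, tpr, _ = roc_curve(y_bin, proba[:, j])
        aucs[lab] = float(auc(fpr, tpr))
        rocs[lab] = list(zip(fpr.tolist(), tpr.tolist()))
    return EvalReport(
        label_names=list(names),
        precision={l: float(p) for l, p in zip(names, prec)},
        recall={l: float(r) for l, r in zip(names, rec)},
        f_score={l: float(f) for l, f in zip(names, f1)},
        auc_per_label=aucs,
        macro_f=float(np.mean(f1)),
        macro_auc=float(np.mean(list(aucs.values()))),
        confusion=conf,
        roc_points=rocs,
        support={l: int(s) for l, s in zip(names, support)},
    )


@dataclass
class CVResult:
    """Per-fold validation reports, the final model, and its holdout report."""

    fold_reports: list[EvalReport]
    holdout_report: EvalReport
    model: ANNModel

    @property
    def mean_fold_macro_f(self) -> float:
        return float(np.mean([r.macro_f for r in self.fold_reports]))

    @property
    def mean_fold_macro_auc(self) -> float:
        return float(np.mean([r.macro_auc for r in self.fold_reports]))


def cross_validate(ds: LabeledDataset, cfg: ANNConfig,
                   split_cfg: SplitConfig) -> CVResult:
    """Stratified holdout + k-fold CV on the train part.

    Each fold report evaluates a model trained on the other folds against
    the held-in validation fold; the final model is trained on the entire
    train part and evaluated once on the untouched holdout.
    """
    train, test, _ = split_dataset(ds, split_cfg)
    y = np.asarray(train.labels)
    skf = StratifiedKFold(n_splits=split_cfg.n_folds, shuffle=True,
                          random_state=split_cfg.seed)
    fold_reports: list[EvalReport] = []
    for k, (tr, val) in enumerate(skf.split(train.features, y)):
        mask = np.zeros(len(train), dtype=bool)
        mask[tr] = True
        fold_model = train_ann(train.subset(mask),
                               ANNConfig(**{**cfg.__dict__,
                                            "seed": cfg.seed + k}))
        fold_reports.append(evaluate(fold_model, train.subset(~mask)))
    final = train_ann(train, cfg)
    holdout_report = evaluate(final, test)
    return CVResult(fold_reports=fold_reports,
                    holdout_report=holdout_report, model=final)


def pairwise_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Brute-force AUC: fraction of correctly ordered (pos, neg) pairs,
    ties counted half.  Independent cross-check for the ROC-based AUC."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    if not pos or not neg:
        raise ValueError("need both classes")
    wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
    return wins / (len(pos) * len(neg))
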