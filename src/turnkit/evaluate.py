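"""Residue-level evaluation: confusion counts, the five standard
turn/non-turn measures, threshold sweeps, ROC/AUC, and chain-level
cross-validation.

With TP/TN/FP/FN counted over residues,

    Ac    = (TP + TN) / N
    Qpred = TP / (TP + FP)
    Sn    = TP / (TP + FN)
    Sp    = TN / (TN + FP)
    MCC   = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Any 0/0 ratio is reported as 0 with its name recorded in the
`undefined` set of the report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .crf import TrainConfig, predict, train
from .features import DEFAULT_OFFSETS, expand_context


@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.TN + other.TN,
                               self.FP + other.FP, self.FN + other.FN)


@dataclass
class MetricsReport:
    Ac: float
    Qpred: float
    Sn: float
    Sp: float
    MCC: float
    undefined: set[str] = field(default_factory=set)


def confusion(pred, truth) -> ConfusionCounts:
    """Count TP/TN/FP/FN over aligned binary label sequences (1 = turn)."""
    pred = np.asarray(pred).astype(np.int64).ravel()
    truth = np.asarray(truth).astype(np.int64).ravel()
    if pred.shape != truth.shape:
        raise ValueError(
            f"length mismatch: pred {pred.shape[0]} vs truth {truth.shape[0]}"
        )
    tp = int(np.sum((pred == 1) & (truth == 1)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num: float, den: float, name: str, undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> MetricsReport:
    """The five turn/non-turn measures from the confusion counts."""
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    undef: set[str] = set()
    ac = (c.TP + c.TN) / c.total
    qpred = _ratio(c.TP, c.TP + c.FP, "Qpred", undef)
    sn = _ratio(c.TP, c.TP + c.FN, "Sn", undef)
    sp = _ratio(c.TN, c.TN + c.FP, "Sp", undef)
    denom = (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    if denom == 0:
        undef.add("MCC")
        mcc = 0.0
    else:
        mcc = (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom)
    return MetricsReport(Ac=ac, Qpred=qpred, Sn=sn, Sp=sp, MCC=mcc,
                         undefined=undef)


def threshold_sweep(probabilities, truth, thresholds
                    ) -> list[tuple[float, MetricsReport]]:
    """Metrics at each decision threshold (ascending).  Raising the
    threshold can only shrink the predicted-turn set, so Sn is
    non-increasing and Sp non-decreasing along the sweep."""
    probabilities = np.asarray(probabilities, dtype=float)
    thresholds = list(thresholds)
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted ascending")
    out = []
    for th in thresholds:
        pred = (probabilities >= th).astype(np.uint8)
        out.append((th, metrics(confusion(pred, truth))))
    return out


def roc_auc(probabilities, truth) -> float:
    """Area under the ROC curve by the rank statistic: the probability
    that a random turn residue outranks a random non-turn residue, ties
    counted 1/2.  Equals the trapezoidal area over all thresholds."""
    probabilities = np.asarray(probabilities, dtype=float)
    truth = np.asarray(truth).astype(bool).ravel()
    pos = probabilities[truth]
    neg = probabilities[~truth]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present for ROC/AUC")
    # O((n+m) log) via rank sums
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def kfold_split(chain_ids, k: int = 5, seed: int = 0) -> list[list]:
    """Deterministic balanced partition of chain identifiers into k folds
    (never splitting residues of one chain across folds).  Fold sizes
    differ by at most one."""
    ids = list(chain_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ids) < k:
        raise ValueError(f"need at least {k} chains for {k}-fold split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    base, extra = divmod(len(ids), k)
    folds = []
    pos = 0
    for f in range(k):
        size = base + (1 if f < extra else 0)
        folds.append([ids[i] for i in order[pos:pos + size]])
        pos += size
    return folds


@dataclass
class CrossValidationResult:
    pooled: MetricsReport
    pooled_counts: ConfusionCounts
    per_fold: list[MetricsReport]
    per_fold_counts: list[ConfusionCounts]
    probabilities: list[np.ndarray]     # held-out posteriors, dataset order
    truths: list[np.ndarray]


def cross_validate(dataset, k: int = 5, train_cfg: TrainConfig | None = None,
                   threshold: float = 0.5, seed: int = 0,
                   offsets=DEFAULT_OFFSETS) -> CrossValidationResult:
    """k-fold cross-validation over chains (micro-averaged).

    `dataset` is a list of ``(FeatureTable, labels)`` pairs.  Context
    expansion, training and prediction happen inside each fold; pooled
    metrics are computed from the summed confusion counts.
    """
    train_cfg = train_cfg or TrainConfig()
    expanded = [expand_context(ft, offsets) for ft, _ in dataset]
    labels = [np.asarray(y, dtype=np.uint8) for _, y in dataset]
    folds = kfold_split(range(len(dataset)), k=k, seed=seed)

    pooled = ConfusionCounts()
    per_fold_counts = []
    probs: list[np.ndarray | None] = [None] * len(dataset)
    for fold in folds:
        test_idx = set(fold)
        train_set = [(expanded[i], labels[i]) for i in range(len(dataset))
                     if i not in test_idx]
        model = train(train_set, train_cfg)
        fc = ConfusionCounts()
        for i in fold:
            res = predict(model, expanded[i], threshold=threshold)
            probs[i] = res.turn_probability
            fc = fc + confusion(res.labels, labels[i])
        per_fold_counts.append(fc)
        pooled = pooled + fc
    return CrossValidationResult(
        pooled=metrics(pooled),
        pooled_counts=pooled,
        per_fold=[metrics(c) for c in per_fold_counts],
        per_fold_counts=per_fold_counts,
        probabilities=[p for p in probs],  # type: ignore[list-item]
        truths=labels,
    )
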