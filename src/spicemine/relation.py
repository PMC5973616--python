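"""Relation classification: positive / negative / no-association.

Features are unigram+bigram counts scaled by TF-IDF with
``idf(t) = log(N / n_t)`` (natural log, no smoothing), where *N* is the
number of training sentences and *n_t* the number containing term *t*.
The default engine is a one-vs-all linear SVM: three binary separators,
prediction by argmax of the decision values.  Class imbalance is handled
by oversampling inside training folds only.  Evaluation reports
per-class precision/recall/F1 from one-vs-rest confusion tables,
overall accuracy, and unweighted macro averages.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from random import Random
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from spicemine.candidates import CandidateInstance

logger = logging.getLogger(__name__)

__all__ = [
    "CLASSES",
    "POSITIVE",
    "NEGATIVE",
    "NO_ASSOCIATION",
    "TfidfFeaturizer",
    "ConfusionMatrix",
    "Metrics",
    "SvmRelationModel",
    "fit_tfidf",
    "oversample",
    "train_svm",
    "evaluate",
    "cross_validate",
    "apply_negative_overrides",
]

POSITIVE = "positive"
NEGATIVE = "negative"
NO_ASSOCIATION = "no-association"
CLASSES = (NO_ASSOCIATION, NEGATIVE, POSITIVE)

#: Oversampling factors mirroring the training regime for the
#: imbalanced association corpus (negatives are the rarest class).
DEFAULT_OVERSAMPLE = {NEGATIVE: 12.0, POSITIVE: 1.35}


def _terms(tokens: Sequence[str]) -> list[str]:
    """Unigram and bigram terms of a token sequence."""
    unigrams = list(tokens)
    bigrams = [f"{a} {b}" for a, b in zip(tokens, tokens[1:])]
    return unigrams + bigrams


class TfidfFeaturizer:
    """Unigram+bigram TF-IDF with idf(t) = log(N / n_t).

    The feature value for term *t* in sentence *s* is
    ``f_{t,s} * log(N / n_t)``; a term present in every sentence thus
    carries zero weight.  Terms unseen at fit time are ignored at
    transform time.
    """

    def __init__(self) -> None:
        self.vocabulary: dict[str, int] = {}
        self.idf: np.ndarray = np.empty(0)

    def fit(self, instances: Sequence[CandidateInstance]) -> "TfidfFeaturizer":
        if not instances:
            raise ValueError("cannot fit TF-IDF on an empty corpus")
        n_docs = len(instances)
        doc_freq: dict[str, int] = {}
        for inst in instances:
            for term in set(_terms(inst.tokens)):
                doc_freq[term] = doc_freq.get(term, 0) + 1
        self.vocabulary = {t: i for i, t in enumerate(sorted(doc_freq))}
        self.idf = np.zeros(len(self.vocabulary))
        for term, idx in self.vocabulary.items():
            self.idf[idx] = math.log(n_docs / doc_freq[term])
        return self

    def transform(self, instances: Sequence[CandidateInstance]) -> sp.csr_matrix:
        if not self.vocabulary:
            raise ValueError("featurizer not fitted")
        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []
        for r, inst in enumerate(instances):
            counts: dict[int, int] = {}
            for term in _terms(inst.tokens):
                idx = self.vocabulary.get(term)
                if idx is not None:
                    counts[idx] = counts.get(idx, 0) + 1
            for idx, tf in counts.items():
                rows.append(r)
                cols.append(idx)
                vals.append(tf * self.idf[idx])
        return sp.csr_matrix(
            (vals, (rows, cols)), shape=(len(instances), len(self.vocabulary))
        )

    def fit_transform(self, instances: Sequence[CandidateInstance]) -> sp.csr_matrix:
        return self.fit(instances).transform(instances)


def fit_tfidf(instances: Sequence[CandidateInstance]) -> TfidfFeaturizer:
    """Fit the TF-IDF model on a training corpus."""
    return TfidfFeaturizer().fit(instances)


def oversample(
    instances: Sequence[CandidateInstance],
    factors: dict[str, float] | None = None,
    seed: int = 0,
) -> list[CandidateInstance]:
    """Oversample classes by the given factors (training folds only).

    A class of size *m* with factor *f* grows to ``round(m * f)``: every
    instance is duplicated ``floor(f) - 1`` extra times and the
    fractional remainder is a seeded uniform sample without replacement.
    """
    factors = DEFAULT_OVERSAMPLE if factors is None else factors
    for cls, f in factors.items():
        if f < 1:
            raise ValueError(f"oversampling factor for {cls!r} must be >= 1, got {f}")
    rng = Random(seed)
    out = list(instances)
    for cls, f in sorted(factors.items()):
        members = [inst for inst in instances if inst.label == cls]
        m = len(members)
        if m == 0 or f == 1:
            continue
        target = round(m * f)
        whole_extra = int(math.floor(f)) - 1
        for _ in range(whole_extra):
            out.extend(members)
        remainder = target - m * (whole_extra + 1)
        if remainder > 0:
            out.extend(rng.sample(members, remainder))
    return out


@dataclass
class ConfusionMatrix:
    """Per-class one-vs-rest 2x2 counts over the three classes."""

    tp: dict[str, int] = field(default_factory=dict)
    fp: dict[str, int] = field(default_factory=dict)
    fn: dict[str, int] = field(default_factory=dict)
    tn: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_labels(
        cls, predictions: Sequence[str], gold: Sequence[str]
    ) -> "ConfusionMatrix":
        if len(predictions) != len(gold):
            raise ValueError("predictions and gold must have equal length")
        for lab in list(predictions) + list(gold):
            if lab not in CLASSES:
                raise ValueError(f"label {lab!r} outside the 3-class set")
        cm = cls()
        for c in CLASSES:
            cm.tp[c] = sum(1 for p, g in zip(predictions, gold) if p == c and g == c)
            cm.fp[c] = sum(1 for p, g in zip(predictions, gold) if p == c and g != c)
            cm.fn[c] = sum(1 for p, g in zip(predictions, gold) if p != c and g == c)
            cm.tn[c] = sum(1 for p, g in zip(predictions, gold) if p != c and g != c)
        return cm


@dataclass
class Metrics:
    """Per-class P/R/F1, overall accuracy, unweighted macro averages."""

    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"undefined {what} (0/0) reported as 0", stacklevel=3)
        return 0.0
    return num / den


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def metrics_from_confusion(cm: ConfusionMatrix, total: int) -> Metrics:
    precision = {
        c: _safe_ratio(cm.tp[c], cm.tp[c] + cm.fp[c], f"precision[{c}]")
        for c in CLASSES
    }
    recall = {
        c: _safe_ratio(cm.tp[c], cm.tp[c] + cm.fn[c], f"recall[{c}]") for c in CLASSES
    }
    f1 = {c: f1_score(precision[c], recall[c]) for c in CLASSES}
    correct = sum(cm.tp[c] for c in CLASSES)
    return Metrics(
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=_safe_ratio(correct, total, "accuracy"),
        macro_precision=sum(precision.values()) / len(CLASSES),
        macro_recall=sum(recall.values()) / len(CLASSES),
        macro_f1=sum(f1.values()) / len(CLASSES),
    )


def evaluate(predictions: Sequence[str], gold: Sequence[str]) -> Metrics:
    """Compute the evaluation metrics from predicted and gold labels."""
    cm = ConfusionMatrix.from_labels(predictions, gold)
    return metrics_from_confusion(cm, len(gold))


@dataclass
class SvmRelationModel:
    """One-vs-all linear SVM over TF-IDF features."""

    featurizer: TfidfFeaturizer
    svm: LinearSVC
    classes: tuple[str, ...]

    def predict(self, instances: Sequence[CandidateInstance]) -> list[str]:
        X = self.featurizer.transform(instances)
        return [str(lab) for lab in self.svm.predict(X)]

    def decision_values(self, instances: Sequence[CandidateInstance]) -> np.ndarray:
        X = self.featurizer.transform(instances)
        scores = self.svm.decision_function(X)
        if scores.ndim == 1:  # two-class edge case
            scores = np.column_stack([-scores, scores])
        return scores


def train_svm(
    instances: Sequence[CandidateInstance],
    c: float = 1.0,
    seed: int = 0,
) -> SvmRelationModel:
    """Train the one-vs-all linear SVM on labeled instances.

    TF-IDF is fitted on the same training instances; prediction is the
    argmax over the per-class decision values.  Deterministic for a
    fixed seed.
    """
    labels = [inst.label for inst in instances]
    present = set(labels)
    if None in present:
        raise ValueError("all training instances must carry a label")
    if len(present) < 2:
        raise ValueError("training data must contain at least 2 classes")
    featurizer = fit_tfidf(instances)
    X = featurizer.transform(instances)
    svm = LinearSVC(C=c, random_state=seed, max_iter=10000)
    svm.fit(X, np.asarray(labels))
    return SvmRelationModel(
        featurizer=featurizer, svm=svm, classes=tuple(svm.classes_)
    )


def cross_validate(
    instances: Sequence[CandidateInstance],
    k: int = 5,
    seed: int = 0,
    c_grid: Sequence[float] = (1.0,),
    oversample_factors: dict[str, float] | None = None,
) -> dict:
    """Stratified k-fold cross-validation with in-fold oversampling.

    Oversampling is applied to the training folds only, so duplicated
    instances never leak across a train/validation boundary.  When a
    grid of SVM cost values is given, each is scored by its mean
    validation macro-F1 and the best is reported.
    """
    labels = [inst.label for inst in instances]
    counts = {c: labels.count(c) for c in set(labels)}
    thin = [c for c, n in counts.items() if n < k]
    if thin:
        raise ValueError(
            f"classes {thin} have fewer than k={k} members; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    instances = list(instances)
    y = np.asarray(labels)
    results: dict[float, list[Metrics]] = {}
    folds = list(skf.split(np.zeros(len(instances)), y))
    for c in c_grid:
        fold_metrics: list[Metrics] = []
        for train_idx, val_idx in folds:
            train = oversample(
                [instances[i] for i in train_idx], oversample_factors, seed=seed
            )
            val = [instances[i] for i in val_idx]
            model = train_svm(train, c=c, seed=seed)
            preds = model.predict(val)
            fold_metrics.append(evaluate(preds, [v.label for v in val]))
        results[c] = fold_metrics
    best_c = max(
        results, key=lambda c: sum(m.macro_f1 for m in results[c]) / len(results[c])
    )
    return {
        "per_fold": results[best_c],
        "selected": {"C": best_c},
        "mean_macro_f1": sum(m.macro_f1 for m in results[best_c]) / k,
        "folds": folds,
    }


def apply_negative_overrides(
    predictions: dict[str, str],
    overrides: dict[str, str] | None = None,
) -> dict[str, str]:
    """Manual-review hook for predicted negative associations.

    ``overrides`` maps instance_id -> "confirm" | "reject"; rejected
    negatives become no-association.  With no override file every
    prediction is accepted as-is (a notice is logged), mirroring a
    manual-cleaning step applied to the rare negative class.
    """
    if not overrides:
        logger.info(
            "no negative-association override file: accepting all predictions"
        )
        return dict(predictions)
    out = dict(predictions)
    for instance_id, action in overrides.items():
        if instance_id not in out:
            logger.warning("override for unknown instance %r ignored", instance_id)
            continue
        if action == "reject" and out[instance_id] == NEGATIVE:
            out[instance_id] = NO_ASSOCIATION
    return out
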