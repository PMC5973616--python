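"""TF-IDF features, oversampling, SVM engine and evaluation metrics."""

import math
import random

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from spicemine.candidates import CandidateInstance
from spicemine.relation import (
    CLASSES,
    NEGATIVE,
    NO_ASSOCIATION,
    POSITIVE,
    apply_negative_overrides,
    cross_validate,
    evaluate,
    fit_tfidf,
    oversample,
    train_svm,
)


def _inst(tokens, label=None, iid="i"):
    return CandidateInstance(
        iid, "d", 0, "S", "M", ["SPICE", "DISEASE"] + list(tokens), label=label
    )


# ---------------------------------------------------------------------------
# TF-IDF
# ---------------------------------------------------------------------------


def test_term_in_every_sentence_has_zero_weight():
    instances = [_inst(["common", f"rare{i}"]) for i in range(4)]
    feats = fit_tfidf(instances)
    X = feats.transform(instances).toarray()
    col = feats.vocabulary["common"]
    assert np.allclose(X[:, col], 0.0)


def test_tfidf_hand_computed_weight():
    # 10 sentences; term "special" appears twice in the first one only
    instances = [_inst(["special", "special"], iid="i0")] + [
        _inst([f"filler{i}"], iid=f"i{i}") for i in range(1, 10)
    ]
    feats = fit_tfidf(instances)
    X = feats.transform(instances).toarray()
    col = feats.vocabulary["special"]
    assert X[0, col] == pytest.approx(2 * math.log(10))


def test_identical_sentences_identical_rows():
    instances = [_inst(["alpha", "beta"]), _inst(["alpha", "beta"]), _inst(["x"])]
    X = fit_tfidf(instances).transform(instances).toarray()
    assert np.array_equal(X[0], X[1])


def test_tfidf_includes_bigrams():
    feats = fit_tfidf([_inst(["a", "b"]), _inst(["b", "a"])])
    assert "a b" in feats.vocabulary
    assert "b a" in feats.vocabulary


def test_tfidf_empty_corpus_rejected():
    with pytest.raises(ValueError):
        fit_tfidf([])


# ---------------------------------------------------------------------------
# oversampling
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("m,factor,expected", [(10, 12.0, 120), (100, 1.35, 135)])
def test_oversample_reaches_rounded_target(m, factor, expected):
    minority = [_inst(["w"], label=NEGATIVE, iid=f"n{i}") for i in range(m)]
    out = oversample(minority, {NEGATIVE: factor}, seed=0)
    assert sum(1 for i in out if i.label == NEGATIVE) == expected


def test_oversample_factor_one_is_identity():
    instances = [_inst(["w"], label=POSITIVE, iid=f"p{i}") for i in range(7)]
    assert oversample(instances, {POSITIVE: 1.0}, seed=0) == instances


def test_oversample_rejects_factor_below_one():
    with pytest.raises(ValueError):
        oversample([_inst(["w"], label=POSITIVE)], {POSITIVE: 0.5})


def test_oversample_leaves_other_classes_untouched():
    instances = [
        _inst(["w"], label=POSITIVE, iid="p0"),
        _inst(["w"], label=NO_ASSOCIATION, iid="z0"),
    ]
    out = oversample(instances, {POSITIVE: 3.0}, seed=1)
    assert sum(1 for i in out if i.label == NO_ASSOCIATION) == 1
    assert sum(1 for i in out if i.label == POSITIVE) == 3


# ---------------------------------------------------------------------------
# SVM engine
# ---------------------------------------------------------------------------


def _toy_corpus(n_per_class=30, seed=0):
    rng = random.Random(seed)
    cues = {
        POSITIVE: ["improves", "alleviates", "protects"],
        NEGATIVE: ["worsens", "aggravates", "harms"],
        NO_ASSOCIATION: ["mentions", "discusses", "lists"],
    }
    out = []
    for cls, words in cues.items():
        for i in range(n_per_class):
            tokens = [rng.choice(words), f"filler{rng.randint(0, 5)}"]
            out.append(_inst(tokens, label=cls, iid=f"{cls}{i}"))
    rng.shuffle(out)
    return out


def test_separable_corpus_reaches_perfect_training_accuracy():
    corpus = _toy_corpus()
    model = train_svm(corpus, seed=0)
    preds = model.predict(corpus)
    assert preds == [i.label for i in corpus]


def test_training_is_deterministic():
    corpus = _toy_corpus()
    m1 = train_svm(corpus, seed=3)
    m2 = train_svm(corpus, seed=3)
    assert m1.predict(corpus) == m2.predict(corpus)
    assert np.allclose(m1.svm.coef_, m2.svm.coef_)


def test_single_class_training_rejected():
    with pytest.raises(ValueError):
        train_svm([_inst(["w"], label=POSITIVE, iid=f"p{i}") for i in range(5)])


def test_permuted_labels_stay_near_majority_baseline():
    rng = random.Random(1)
    corpus = _toy_corpus(n_per_class=100, seed=1)
    labels = [i.label for i in corpus]
    rng.shuffle(labels)
    for inst, lab in zip(corpus, labels):
        inst.label = lab
    train, test = corpus[:200], corpus[200:]
    model = train_svm(train, seed=1)
    acc = evaluate(model.predict(test), [t.label for t in test]).accuracy
    gold = [t.label for t in test]
    baseline = max(gold.count(c) for c in CLASSES) / len(gold)
    assert abs(acc - baseline) <= 0.15


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------


def test_perfect_predictions_give_all_ones():
    gold = [POSITIVE, NEGATIVE, NO_ASSOCIATION] * 4
    m = evaluate(gold, gold)
    assert m.accuracy == 1.0
    assert m.macro_f1 == 1.0
    assert all(v == 1.0 for v in m.f1.values())


def test_unknown_label_rejected():
    with pytest.raises(ValueError):
        evaluate(["maybe"], [POSITIVE])


@pytest.mark.filterwarnings("ignore:undefined")
def test_metrics_agree_with_independent_oracle():
    """Random label vectors: per-class P/R/F1 and macro averages match
    an independent confusion-matrix implementation."""
    rng = random.Random(7)
    for _ in range(200):
        n = rng.randint(1, 40)
        gold = rng.choices(CLASSES, k=n)
        pred = rng.choices(CLASSES, k=n)
        m = evaluate(pred, gold)
        p, r, f, _ = precision_recall_fscore_support(
            gold, pred, labels=list(CLASSES), average=None, zero_division=0
        )
        for i, c in enumerate(CLASSES):
            assert m.precision[c] == pytest.approx(p[i])
            assert m.recall[c] == pytest.approx(r[i])
            assert m.f1[c] == pytest.approx(f[i])
        assert m.macro_f1 == pytest.approx(float(np.mean(f)))
        assert m.accuracy == pytest.approx(
            sum(1 for a, b in zip(pred, gold) if a == b) / n
        )


@pytest.mark.filterwarnings("ignore:undefined")
def test_f1_within_harmonic_mean_bounds():
    rng = random.Random(3)
    for _ in range(300):
        n = rng.randint(3, 30)
        gold = rng.choices(CLASSES, k=n)
        pred = rng.choices(CLASSES, k=n)
        m = evaluate(pred, gold)
        for c in CLASSES:
            assert min(m.precision[c], m.recall[c]) - 1e-12 <= m.f1[c]
            assert m.f1[c] <= max(m.precision[c], m.recall[c]) + 1e-12


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def test_folds_disjoint_and_covering():
    corpus = _toy_corpus(n_per_class=20)
    result = cross_validate(corpus, k=5, seed=0)
    seen = []
    for _, val_idx in result["folds"]:
        seen.extend(val_idx)
    assert sorted(seen) == list(range(len(corpus)))
    assert len(result["per_fold"]) == 5


def test_same_seed_identical_folds():
    corpus = _toy_corpus(n_per_class=15)
    f1 = [tuple(v) for _, v in cross_validate(corpus, k=3, seed=9)["folds"]]
    f2 = [tuple(v) for _, v in cross_validate(corpus, k=3, seed=9)["folds"]]
    assert f1 == f2


def test_oversampled_duplicates_never_leak_into_validation():
    corpus = _toy_corpus(n_per_class=20)
    result = cross_validate(
        corpus, k=4, seed=2, oversample_factors={NEGATIVE: 3.0}
    )
    for train_idx, val_idx in result["folds"]:
        train = oversample(
            [corpus[i] for i in train_idx], {NEGATIVE: 3.0}, seed=2
        )
        val_ids = {corpus[i].instance_id for i in val_idx}
        assert not val_ids & {t.instance_id for t in train}


def test_class_thinner_than_k_rejected():
    corpus = _toy_corpus(n_per_class=3)
    with pytest.raises(ValueError, match="smaller k"):
        cross_validate(corpus, k=5)


def test_negative_override_hook():
    preds = {"a": NEGATIVE, "b": NEGATIVE, "c": POSITIVE}
    assert apply_negative_overrides(preds) == preds
    out = apply_negative_overrides(preds, {"a": "reject", "b": "confirm"})
    assert out == {"a": NO_ASSOCIATION, "b": NEGATIVE, "c": POSITIVE}
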