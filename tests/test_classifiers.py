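"""Gradient correctness, training protocol, and architecture sanity."""

import time

import numpy as np
import pytest

from quorum import _net
from quorum.classifiers import (
    TrainConfig,
    TrainedClassifier,
    predict_label,
    train_classifier,
)
from quorum.corpus import Corpus, stratified_split
from quorum.synthetic import GeneratorConfig, generate_corpus


# ---------------------------------------------------------------------------
# finite-difference gradient checks
# ---------------------------------------------------------------------------

def _nets():
    return {
        "textcnn": _net.TextCNNNet(30, 8, (2, 3, 4), 5),
        "fasttext": _net.FastTextNet(30, 8, 2, 64),
        "dpcnn": _net.DPCNNNet(30, 8, 2, 6),
    }


@pytest.mark.parametrize("arch", ["textcnn", "fasttext", "dpcnn"])
def test_backward_matches_finite_differences(arch, rng):
    """Analytic gradients agree with central differences for every
    parameter tensor (float64, biases nudged off relu kinks)."""
    net = _nets()[arch]
    ids = rng.integers(1, 30, size=(4, 17))
    ids[0, 12:] = 0
    y = np.array([0, 1, 1, 0])
    params = {k: v.astype(np.float64) for k, v in
              net.init_params(np.random.default_rng(1)).items()}
    for k, v in params.items():
        if k.startswith("b"):  # move biases off the relu kink at exactly 0
            params[k] = v + rng.normal(0.05, 0.01, size=v.shape)
    logits, cache = net.forward(params, ids)
    _, dlogits = _net.softmax_cross_entropy(logits, y)
    grads = net.backward(params, cache, dlogits)
    for k, P in params.items():
        flat = P.reshape(-1)
        gflat = grads[k].reshape(-1)
        for ix in rng.choice(flat.size, size=min(8, flat.size), replace=False):
            if k == "E" and ix < P.shape[-1]:  # pad row is frozen
                continue
            eps = 1e-6
            old = flat[ix]
            flat[ix] = old + eps
            l1, _ = _net.softmax_cross_entropy(net.forward(params, ids)[0], y)
            flat[ix] = old - eps
            l2, _ = _net.softmax_cross_entropy(net.forward(params, ids)[0], y)
            flat[ix] = old
            num = (l1 - l2) / (2 * eps)
            assert gflat[ix] == pytest.approx(num, rel=1e-4, abs=1e-7), (k, ix)


# ---------------------------------------------------------------------------
# training on a separable corpus
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def separable():
    """Small, balanced, strongly separable corpus with train/val/test views."""
    config = GeneratorConfig(
        n_positive=30, n_negative=30,
        posts_per_user_mean_positive=4, posts_per_user_mean_negative=4,
        post_length_mean_positive=8, post_length_mean_negative=8,
        vocab_shared=60, signal_strength=0.5, hidden_fraction=0.0,
        treehole_post_rate=0.2, seed=5,
    )
    corpus, _ = generate_corpus(config)
    split = stratified_split(corpus, (0.6, 0.2, 0.2), seed=5)
    return {part: split.partition_corpus(corpus, part).users
            for part in ("train", "val", "test")}


@pytest.mark.parametrize("arch", ["textcnn", "fasttext", "dpcnn"])
def test_architectures_fit_separable_data(separable, arch):
    """All three architectures reach validation F1 >= 0.95 on a corpus whose
    classes use disjoint signal vocabularies (batch size scaled to the
    fixture so each epoch takes several optimiser steps)."""
    clf = train_classifier(separable["train"], separable["val"],
                           TrainConfig(architecture=arch, seed=2, batch_size=8))
    assert clf.validation_f1 >= 0.95


def test_best_checkpoint_semantics(separable):
    clf = train_classifier(separable["train"], separable["val"],
                           TrainConfig(architecture="fasttext", seed=3, batch_size=8))
    assert clf.validation_f1 == pytest.approx(max(v for _, _, v in clf.training_log))


def test_default_batch_size_is_128():
    assert TrainConfig().batch_size == 128


def test_epoch_defaults_per_architecture():
    assert TrainConfig(architecture="textcnn").resolved_epochs == 20
    assert TrainConfig(architecture="dpcnn").resolved_epochs == 20
    assert TrainConfig(architecture="fasttext").resolved_epochs == 50


def test_seed_determinism(separable):
    cfg = TrainConfig(architecture="fasttext", seed=7, batch_size=8)
    a = train_classifier(separable["train"], separable["val"], cfg)
    b = train_classifier(separable["train"], separable["val"], cfg)
    assert np.array_equal(a.predict_users(separable["test"]),
                          b.predict_users(separable["test"]))
    assert a.training_log == b.training_log


def test_predict_label_on_separable_positive(separable):
    clf = train_classifier(separable["train"], separable["val"],
                           TrainConfig(architecture="fasttext", seed=2, batch_size=8))
    positives = [u for u in separable["test"] if u.label == "suicidal"]
    preds = {predict_label(clf, u) for u in positives}
    assert preds == {"suicidal"}
    # repeat call gives the identical answer
    assert predict_label(clf, positives[0]) == predict_label(clf, positives[0])


def test_dummy_trains_fast_and_reproducibly(separable):
    t0 = time.time()
    cfg = TrainConfig(architecture="dummy", seed=1)
    a = train_classifier(separable["train"], separable["val"], cfg)
    assert time.time() - t0 < 1.0
    b = train_classifier(separable["train"], separable["val"], cfg)
    assert np.array_equal(a.predict_users(separable["test"]),
                          b.predict_users(separable["test"]))
    assert a.validation_f1 >= 0.95


def test_checkpoint_round_trip(tmp_path, separable):
    clf = train_classifier(separable["train"], separable["val"],
                           TrainConfig(architecture="fasttext", seed=4, batch_size=8))
    clf.save(tmp_path / "ckpt")
    back = TrainedClassifier.load(tmp_path / "ckpt")
    assert back.architecture == "fasttext"
    assert back.validation_f1 == clf.validation_f1
    assert np.array_equal(back.predict_users(separable["test"]),
                          clf.predict_users(separable["test"]))


def test_errors(separable):
    with pytest.raises(ValueError):
        TrainConfig(architecture="transformer")
    with pytest.raises(ValueError):
        train_classifier([], separable["val"], TrainConfig())
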