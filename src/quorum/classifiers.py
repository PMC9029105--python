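"""Base text classifiers and their training protocol.

Three neural architectures (TextCNN, FastText, DPCNN — see
:mod:`quorum._net`) plus a deterministic ``dummy`` bag-of-words logistic
scorer that exists as a fast test double for the ensemble machinery.

Training uses randomly initialised word vectors learned end-to-end,
cross-entropy loss, minibatch Adam, and best-checkpoint early stopping on
validation F1: the parameters reported are those of the epoch with the
highest validation F1, and training stops after ``early_stopping_patience``
non-improving epochs.  Everything is seeded: weight initialisation, batch
shuffling, and any truncation sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from . import _net
from .corpus import Corpus, POSITIVE_LABEL, NEGATIVE_LABEL, UserRecord
from .encoding import (
    Tokenizer,
    Vocabulary,
    build_vocabulary,
    concat_posts,
    encode_batch,
    whitespace_tokenizer,
)
from .sampling import BalancedSubset

ARCHITECTURES = ("textcnn", "fasttext", "dpcnn", "dummy")
NEURAL_ARCHITECTURES = ("textcnn", "fasttext", "dpcnn")

_DEFAULT_EPOCHS = {"textcnn": 20, "dpcnn": 20, "fasttext": 50, "dummy": 1}
# Adam step sizes found stable per architecture at these desk-scale widths
_DEFAULT_LR = {"textcnn": 5e-3, "dpcnn": 1e-3, "fasttext": 1e-2, "dummy": 0.0}


@dataclass
class TrainConfig:
    """Hyperparameters for one base classifier.

    Epoch defaults are architecture-specific (20 for the CNNs, 50 for
    FastText); batch size defaults to 128.  Remaining sizes are desk-scale
    defaults chosen for CPU training and are freely overridable.
    """

    architecture: str = "textcnn"
    epochs: int | None = None
    batch_size: int = 128
    embedding_dim: int = 32
    learning_rate: float | None = None
    early_stopping_patience: int = 5
    max_len: int = 256
    truncation: str = "head"
    seed: int = 0
    # textcnn
    kernel_sizes: tuple[int, ...] = (2, 3, 4)
    n_filters: int = 32
    # fasttext
    fasttext_ngrams: int = 2
    fasttext_buckets: int = 2048
    # dpcnn
    dpcnn_blocks: int = 3
    dpcnn_filters: int = 32

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.epochs is not None and self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @property
    def resolved_epochs(self) -> int:
        return self.epochs if self.epochs is not None else _DEFAULT_EPOCHS[self.architecture]

    @property
    def resolved_learning_rate(self) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return _DEFAULT_LR[self.architecture]

    def replace(self, **kw) -> "TrainConfig":
        data = asdict(self)
        data.update(kw)
        data["kernel_sizes"] = tuple(data["kernel_sizes"])
        return TrainConfig(**data)


@dataclass
class TrainedClassifier:
    """A trained base classifier c_pq with its best-checkpoint parameters."""

    architecture: str
    vocabulary: Vocabulary
    config: TrainConfig
    params: dict[str, np.ndarray]
    pad_len: int
    validation_f1: float
    training_log: list[tuple[int, float, float]] = field(default_factory=list)

    def _net_for(self):
        return _make_net(self.architecture, len(self.vocabulary), self.config)

    def predict_users(self, users: Sequence[UserRecord],
                      tokenizer: Tokenizer = whitespace_tokenizer) -> np.ndarray:
        """Hard 0/1 predictions (1 = positive class) for a batch of users."""
        for u in users:
            if not u.posts:
                raise ValueError(f"user {u.user_id!r} has no posts")
        ids, _ = encode_batch(users, self.vocabulary, self.pad_len,
                              self.config.truncation, tokenizer)
        if self.architecture == "dummy":
            scores = _bow_counts(ids, len(self.vocabulary)) @ self.params["w"] + self.params["b"]
            return (scores > 0).astype(np.int64)
        net = self._net_for()
        logits = _net.predict_logits(net, self.params, ids)
        return logits.argmax(axis=1)

    def save(self, prefix: str | Path) -> None:
        """Versioned binary checkpoint (.npz) + JSON sidecar (.json)."""
        prefix = Path(prefix)
        np.savez(prefix.with_suffix(".npz"), **self.params)
        tokens = [t for t, _ in sorted(self.vocabulary.token_to_id.items(), key=lambda kv: kv[1])]
        sidecar = {
            "format_version": 1,
            "architecture": self.architecture,
            "config": asdict(self.config),
            "pad_len": self.pad_len,
            "validation_f1": self.validation_f1,
            "training_log": self.training_log,
            "vocabulary": tokens,
            "min_frequency": self.vocabulary.min_frequency,
        }
        prefix.with_suffix(".json").write_text(
            json.dumps(sidecar, ensure_ascii=False), encoding="utf-8")

    @classmethod
    def load(cls, prefix: str | Path) -> "TrainedClassifier":
        prefix = Path(prefix)
        sidecar = json.loads(prefix.with_suffix(".json").read_text(encoding="utf-8"))
        cfg = sidecar["config"]
        cfg["kernel_sizes"] = tuple(cfg["kernel_sizes"])
        config = TrainConfig(**cfg)
        vocab = Vocabulary({t: i for i, t in enumerate(sidecar["vocabulary"])},
                           min_frequency=sidecar["min_frequency"])
        with np.load(prefix.with_suffix(".npz")) as data:
            params = {k: data[k] for k in data.files}
        return cls(sidecar["architecture"], vocab, config, params,
                   sidecar["pad_len"], sidecar["validation_f1"],
                   [tuple(row) for row in sidecar["training_log"]])


def predict_label(classifier: TrainedClassifier, user: UserRecord,
                  tokenizer: Tokenizer = whitespace_tokenizer) -> str:
    """Predicted class label for one user (deterministic per classifier)."""
    pred = classifier.predict_users([user], tokenizer)[0]
    return POSITIVE_LABEL if pred == 1 else NEGATIVE_LABEL


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _make_net(architecture: str, vocab_size: int, config: TrainConfig):
    if architecture == "textcnn":
        return _net.TextCNNNet(vocab_size, config.embedding_dim,
                               config.kernel_sizes, config.n_filters)
    if architecture == "fasttext":
        return _net.FastTextNet(vocab_size, config.embedding_dim,
                                config.fasttext_ngrams, config.fasttext_buckets)
    if architecture == "dpcnn":
        return _net.DPCNNNet(vocab_size, config.embedding_dim,
                             config.dpcnn_blocks, config.dpcnn_filters)
    raise ValueError(f"unknown architecture {architecture!r}")


def _labels(users: Sequence[UserRecord]) -> np.ndarray:
    return np.array([1 if u.label == POSITIVE_LABEL else 0 for u in users], dtype=np.int64)


def _binary_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0


def _bow_counts(ids: np.ndarray, vocab_size: int) -> np.ndarray:
    X = np.zeros((len(ids), vocab_size))
    for i, row in enumerate(ids):
        row = row[row != _net.PAD_ID]
        np.add.at(X[i], row, 1.0)
    return X


def _pad_length(users: Sequence[UserRecord], config: TrainConfig,
                tokenizer: Tokenizer) -> int:
    longest = max(len(concat_posts(u, tokenizer)) for u in users)
    floor = max(config.kernel_sizes) if config.architecture == "textcnn" else 4
    return max(min(config.max_len, longest), floor)


def train_classifier(
    train_users: Sequence[UserRecord],
    val_users: Sequence[UserRecord],
    config: TrainConfig,
    vocabulary: Vocabulary | None = None,
    tokenizer: Tokenizer = whitespace_tokenizer,
) -> TrainedClassifier:
    """Train one base classifier on explicit train/validation user lists.

    Documents are padded to the longest training/validation document,
    capped at ``config.max_len``; the pad length is stored so later
    predictions are independent of batch composition.
    """
    if not train_users or not val_users:
        raise ValueError("training and validation sets must be nonempty")
    if vocabulary is None:
        vocabulary = build_vocabulary(Corpus(list(train_users), name="train"),
                                      tokenizer=tokenizer)
    if len(vocabulary) <= 2:
        raise ValueError("vocabulary is empty (only special tokens)")

    pad_len = _pad_length(list(train_users) + list(val_users), config, tokenizer)
    Xtr, _ = encode_batch(train_users, vocabulary, pad_len, config.truncation, tokenizer)
    ytr = _labels(train_users)
    Xva, _ = encode_batch(val_users, vocabulary, pad_len, config.truncation, tokenizer)
    yva = _labels(val_users)

    if config.architecture == "dummy":
        return _train_dummy(Xtr, ytr, Xva, yva, vocabulary, config, pad_len)

    net = _make_net(config.architecture, len(vocabulary), config)
    rng = np.random.default_rng(config.seed)
    params = net.init_params(rng)
    optim = _net.Adam(params, lr=config.resolved_learning_rate)

    best_f1 = -1.0
    best_params: dict[str, np.ndarray] = {k: v.copy() for k, v in params.items()}
    log: list[tuple[int, float, float]] = []
    stale = 0
    for epoch in range(1, config.resolved_epochs + 1):
        order = rng.permutation(len(Xtr))
        losses = []
        for i in range(0, len(order), config.batch_size):
            batch = order[i : i + config.batch_size]
            logits, cache = net.forward(params, Xtr[batch])
            loss, dlogits = _net.softmax_cross_entropy(logits, ytr[batch])
            grads = net.backward(params, cache, dlogits)
            optim.step(grads)
            losses.append(loss)
        val_pred = _net.predict_logits(net, params, Xva).argmax(axis=1)
        val_f1 = _binary_f1(yva, val_pred)
        log.append((epoch, float(np.mean(losses)), val_f1))
        if val_f1 > best_f1 + 1e-12:
            best_f1 = val_f1
            best_params = {k: v.copy() for k, v in params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.early_stopping_patience:
                break
    return TrainedClassifier(config.architecture, vocabulary, config,
                             best_params, pad_len, best_f1, log)


def _train_dummy(Xtr, ytr, Xva, yva, vocabulary, config, pad_len) -> TrainedClassifier:
    # convex bag-of-words logistic fit: deterministic, near-instant
    counts = _bow_counts(Xtr, len(vocabulary))
    clf = LogisticRegression(max_iter=500)
    if len(np.unique(ytr)) < 2:
        raise ValueError("dummy classifier needs both classes in training data")
    clf.fit(counts, ytr)
    w = clf.coef_[0]
    b = float(clf.intercept_[0])
    val_pred = (_bow_counts(Xva, len(vocabulary)) @ w + b > 0).astype(np.int64)
    val_f1 = _binary_f1(yva, val_pred)
    params = {"w": w, "b": np.array(b)}
    return TrainedClassifier("dummy", vocabulary, config, params, pad_len,
                             val_f1, [(1, 0.0, val_f1)])


def train_base_classifier(
    subset: BalancedSubset,
    train_corpus: Corpus,
    val_view: BalancedSubset | Sequence[UserRecord],
    config: TrainConfig,
    val_corpus: Corpus | None = None,
    vocabulary: Vocabulary | None = None,
    tokenizer: Tokenizer = whitespace_tokenizer,
) -> TrainedClassifier:
    """Train one base classifier on a balanced subset D_p.

    ``val_view`` is either a balanced validation subset (resolved against
    ``val_corpus``) or an explicit list of validation users.
    """
    train_users = subset.view(train_corpus).users
    if isinstance(val_view, BalancedSubset):
        if val_corpus is None:
            raise ValueError("val_corpus required when val_view is a BalancedSubset")
        val_users = val_view.view(val_corpus).users
    else:
        val_users = list(val_view)
    return train_classifier(train_users, val_users, config, vocabulary, tokenizer)
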