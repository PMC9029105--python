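"""Document encoding: post concatenation, vocabulary, integer id sequences.

A user's document is the concatenation of their posts in stored order, with
a separator token between posts.  Tokenisation is pluggable (default:
whitespace split), so a Chinese word segmenter can be dropped in without
touching the rest of the pipeline.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .corpus import Corpus, UserRecord

Tokenizer = Callable[[str], list[str]]

PAD_ID = 0
UNK_ID = 1
PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"
SEP_TOKEN = "<sep>"


def whitespace_tokenizer(text: str) -> list[str]:
    return text.split()


def concat_posts(user: UserRecord, tokenizer: Tokenizer = whitespace_tokenizer) -> list[str]:
    """Tokens of all posts in order, with one separator token between posts."""
    if not user.posts:
        raise ValueError(f"user {user.user_id!r} has no posts")
    tokens: list[str] = []
    for i, post in enumerate(user.posts):
        if i:
            tokens.append(SEP_TOKEN)
        tokens.extend(tokenizer(post.text))
    return tokens


@dataclass
class Vocabulary:
    """Token → id mapping with reserved padding (0) and unknown (1) ids."""

    token_to_id: dict[str, int]
    min_frequency: int = 1

    def __len__(self) -> int:
        return len(self.token_to_id)

    def __getitem__(self, token: str) -> int:
        return self.token_to_id.get(token, UNK_ID)

    def encode_tokens(self, tokens: Sequence[str]) -> np.ndarray:
        get = self.token_to_id.get
        return np.fromiter((get(t, UNK_ID) for t in tokens), dtype=np.int64, count=len(tokens))


def build_vocabulary(
    corpus: Corpus,
    min_frequency: int = 1,
    tokenizer: Tokenizer = whitespace_tokenizer,
) -> Vocabulary:
    """Frequency-filtered vocabulary, deterministically ordered.

    Tokens with corpus frequency >= ``min_frequency`` receive ids from 2
    upward, ordered by (frequency desc, token asc); 0 and 1 are reserved for
    padding and unknown.
    """
    counts: Counter[str] = Counter()
    for user in corpus.users:
        if user.posts:
            counts.update(concat_posts(user, tokenizer))
    mapping = {PAD_TOKEN: PAD_ID, UNK_TOKEN: UNK_ID}
    kept = sorted(
        (t for t, c in counts.items() if c >= min_frequency),
        key=lambda t: (-counts[t], t),
    )
    for i, tok in enumerate(kept, start=2):
        mapping[tok] = i
    return Vocabulary(mapping, min_frequency=min_frequency)


@dataclass
class EncodedDocument:
    """Fixed-length id sequence for one user document."""

    token_ids: np.ndarray
    true_length: int
    user_id: str = ""

    def __post_init__(self) -> None:
        self.token_ids = np.asarray(self.token_ids, dtype=np.int64)
        if self.true_length > len(self.token_ids):
            raise ValueError("true_length exceeds padded length")


def encode_document(
    user: UserRecord,
    vocab: Vocabulary,
    max_len: int,
    truncation: str = "head",
    tokenizer: Tokenizer = whitespace_tokenizer,
    rng: np.random.Generator | None = None,
) -> EncodedDocument:
    """Encode a user's concatenated posts to a padded/truncated id vector.

    ``truncation`` is ``head`` (keep the first max_len tokens), ``tail``
    (keep the last), or ``uniform`` (seeded uniform subsample preserving
    order; requires ``rng``).
    """
    tokens = concat_posts(user, tokenizer)
    if len(tokens) > max_len:
        if truncation == "head":
            tokens = tokens[:max_len]
        elif truncation == "tail":
            tokens = tokens[-max_len:]
        elif truncation == "uniform":
            if rng is None:
                raise ValueError("uniform truncation requires an rng")
            idx = np.sort(rng.choice(len(tokens), size=max_len, replace=False))
            tokens = [tokens[i] for i in idx]
        else:
            raise ValueError(f"unknown truncation policy {truncation!r}")
    ids = np.full(max_len, PAD_ID, dtype=np.int64)
    ids[: len(tokens)] = vocab.encode_tokens(tokens)
    return EncodedDocument(ids, true_length=len(tokens), user_id=user.user_id)


def encode_batch(
    users: Sequence[UserRecord],
    vocab: Vocabulary,
    max_len: int,
    truncation: str = "head",
    tokenizer: Tokenizer = whitespace_tokenizer,
) -> tuple[np.ndarray, np.ndarray]:
    """(ids, lengths) matrix for a batch of users, padded to ``max_len``."""
    ids = np.full((len(users), max_len), PAD_ID, dtype=np.int64)
    lengths = np.zeros(len(users), dtype=np.int64)
    for i, u in enumerate(users):
        doc = encode_document(u, vocab, max_len, truncation, tokenizer)
        ids[i] = doc.token_ids
        lengths[i] = doc.true_length
    return ids, lengths
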