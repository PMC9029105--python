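"""Domain types for user-level social-media corpora and their on-disk format.

The unit of classification is the *user*: a labelled, ordered sequence of
posts.  Each post carries a provenance tag (``tree_hole`` for posts
synchronised from a semi-anonymous disclosure venue, ``ordinary`` for the
user's normal timeline, ``system`` for platform-generated messages).  Corpora
are stored as JSON Lines, one user object per line, which keeps files
streamable and diffable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

SOURCES = ("tree_hole", "ordinary", "system")
LABELS = ("suicidal", "non_suicidal")

#: the positive (minority, screening-relevant) class
POSITIVE_LABEL = "suicidal"
NEGATIVE_LABEL = "non_suicidal"

PARTITIONS = ("train", "val", "test")


class CorpusError(ValueError):
    """Raised for schema violations in corpus files or objects."""


@dataclass(frozen=True)
class Post:
    """One social-media message.

    Parameters
    ----------
    text : str
        Unicode body of the post.
    source : str
        Provenance tag, one of ``tree_hole``, ``ordinary``, ``system``.
    created_at : str, optional
        ISO-8601 timestamp, if known.
    """

    text: str
    source: str = "ordinary"
    created_at: str | None = None

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise CorpusError(f"unknown post source {self.source!r}; expected one of {SOURCES}")


@dataclass
class UserRecord:
    """A labelled user with an ordered post sequence (the classification unit)."""

    user_id: str
    posts: list[Post]
    label: str | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in LABELS:
            raise CorpusError(f"unknown label {self.label!r} for user {self.user_id!r}")

    @property
    def n_posts(self) -> int:
        return len(self.posts)

    @property
    def is_positive(self) -> bool:
        return self.label == POSITIVE_LABEL


@dataclass
class Corpus:
    """A named collection of users with unique ids."""

    users: list[UserRecord] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for u in self.users:
            if u.user_id in seen:
                raise CorpusError(f"duplicate user_id {u.user_id!r}")
            seen.add(u.user_id)

    def __len__(self) -> int:
        return len(self.users)

    def __iter__(self) -> Iterator[UserRecord]:
        return iter(self.users)

    def by_id(self, user_id: str) -> UserRecord:
        for u in self.users:
            if u.user_id == user_id:
                return u
        raise KeyError(user_id)

    def subset(self, user_ids: Iterable[str], name: str | None = None) -> "Corpus":
        """Users with the given ids, in the order the ids are supplied.

        Ids may repeat (oversampling views); repeated users get a fresh
        ``#dupK`` suffix so the result is still a valid corpus.
        """
        index = {u.user_id: u for u in self.users}
        out: list[UserRecord] = []
        counts: dict[str, int] = {}
        for uid in user_ids:
            u = index[uid]
            k = counts.get(uid, 0)
            counts[uid] = k + 1
            if k == 0:
                out.append(u)
            else:
                out.append(UserRecord(f"{uid}#dup{k}", list(u.posts), u.label))
        return Corpus(out, name if name is not None else self.name)

    def positive_users(self) -> list[UserRecord]:
        return [u for u in self.users if u.label == POSITIVE_LABEL]

    def negative_users(self) -> list[UserRecord]:
        return [u for u in self.users if u.label == NEGATIVE_LABEL]

    @property
    def n_positive(self) -> int:
        return len(self.positive_users())

    @property
    def n_negative(self) -> int:
        return len(self.negative_users())


@dataclass
class SplitAssignment:
    """Mapping of every corpus user to exactly one of train/val/test."""

    assignment: dict[str, str]

    def __getitem__(self, user_id: str) -> str:
        return self.assignment[user_id]

    def users_in(self, corpus: Corpus, partition: str) -> list[UserRecord]:
        if partition not in PARTITIONS:
            raise CorpusError(f"unknown partition {partition!r}")
        return [u for u in corpus.users if self.assignment[u.user_id] == partition]

    def partition_corpus(self, corpus: Corpus, partition: str) -> Corpus:
        return Corpus(self.users_in(corpus, partition), name=f"{corpus.name}:{partition}")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for uid, part in self.assignment.items():
                fh.write(f"{uid}\t{part}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SplitAssignment":
        assignment: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                uid, part = line.rstrip("\n").split("\t")
                assignment[uid] = part
        return cls(assignment)


# ---------------------------------------------------------------------------
# JSON Lines I/O
# ---------------------------------------------------------------------------

def _post_to_dict(p: Post) -> dict:
    return {"text": p.text, "source": p.source, "created_at": p.created_at}


def _user_to_dict(u: UserRecord) -> dict:
    return {
        "user_id": u.user_id,
        "label": u.label,
        "posts": [_post_to_dict(p) for p in u.posts],
    }


def _user_from_dict(obj: dict, lineno: int) -> UserRecord:
    if not isinstance(obj, dict):
        raise CorpusError(f"line {lineno}: expected a JSON object")
    for key in ("user_id", "posts"):
        if key not in obj:
            raise CorpusError(f"line {lineno}: missing required field {key!r}")
    posts = []
    for j, p in enumerate(obj["posts"]):
        if "text" not in p:
            raise CorpusError(f"line {lineno}: post {j} missing 'text'")
        posts.append(
            Post(
                text=p["text"],
                source=p.get("source", "ordinary"),
                created_at=p.get("created_at"),
            )
        )
    return UserRecord(user_id=obj["user_id"], posts=posts, label=obj.get("label"))


def read_corpus(path: str | Path, name: str | None = None) -> Corpus:
    """Read a JSON Lines corpus file (one user object per line).

    Raises :class:`CorpusError` naming the offending line for malformed
    records, and for duplicate user ids.
    """
    path = Path(path)
    users: list[UserRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"line {lineno}: invalid JSON ({exc.msg})") from exc
            users.append(_user_from_dict(obj, lineno))
    return Corpus(users, name=name if name is not None else path.stem)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as JSON Lines; ``read_corpus`` round-trips it exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        for u in corpus.users:
            fh.write(json.dumps(_user_to_dict(u), ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------

def _partition_sizes(n: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    # Validation and test shares are rounded half-down; the remainder goes to
    # train.  This matches the published per-class 8:1:1 counts for class
    # sizes 1606 (-> 1284/161/161) and 2915 (-> 2333/291/291).
    sizes = []
    for r in ratios[1:]:
        x = r * n
        frac = x - math.floor(x)
        if abs(frac - 0.5) < 1e-9:
            sizes.append(math.floor(x))
        else:
            sizes.append(math.floor(x + 0.5))
    n_val, n_test = sizes
    n_train = n - n_val - n_test
    if n_train < 0:
        raise CorpusError("split ratios allocate more users than available")
    return n_train, n_val, n_test


def stratified_split(
    corpus: Corpus,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Assign each user to train/val/test, stratified by class label.

    Every user must be labelled.  Within each class the partition sizes
    follow ``ratios`` with validation/test shares rounded half-down and the
    remainder assigned to train; membership is a seeded uniform shuffle.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise CorpusError(f"ratios must sum to 1, got {ratios}")
    if any(r < 0 for r in ratios):
        raise CorpusError("ratios must be nonnegative")
    for u in corpus.users:
        if u.label is None:
            raise CorpusError(f"user {u.user_id!r} is unlabelled; cannot stratify")

    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for label in LABELS:
        ids = [u.user_id for u in corpus.users if u.label == label]
        if not ids:
            continue
        n_train, n_val, n_test = _partition_sizes(len(ids), tuple(ratios))
        order = rng.permutation(len(ids))
        for rank, idx in enumerate(order):
            if rank < n_train:
                part = "train"
            elif rank < n_train + n_val:
                part = "val"
            else:
                part = "test"
            assignment[ids[idx]] = part
    # preserve corpus order in the mapping for stable serialisation
    ordered = {u.user_id: assignment[u.user_id] for u in corpus.users}
    return SplitAssignment(ordered)
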