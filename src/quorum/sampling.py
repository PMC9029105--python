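"""Balanced sub-dataset construction and resampling baselines.

An imbalanced training corpus D is turned into n balanced sub-datasets
D_1 … D_n, each containing *all* minority-class users plus an equal-sized
sample of majority-class users.  Two strategies are provided:

``independent_sample``
    each subset's majority sample is drawn independently without
    replacement.  Samples may overlap across subsets — unavoidable whenever
    n·|minority| exceeds |majority|, which is the regime this design targets
    (e.g. three subsets of 1284 from 2333 majority users).

``disjoint_cycle``
    majority users are dealt round-robin from a seeded shuffle, recycling
    (with a fresh shuffle) only once all have been dealt.  Whenever
    n·|minority| ≥ |majority| every majority user lands in at least one
    subset, realising the D = D_1 ∪ … ∪ D_n coverage reading.

Classical oversampling (duplicate whole minority users) and undersampling
(drop majority users) baselines are included for comparison experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import Corpus, CorpusError, UserRecord

STRATEGIES = ("independent_sample", "disjoint_cycle")


def _classes(corpus: Corpus) -> tuple[list[str], list[str]]:
    """(minority_ids, majority_ids); ties resolve to positive = minority."""
    pos = [u.user_id for u in corpus.positive_users()]
    neg = [u.user_id for u in corpus.negative_users()]
    if not pos or not neg:
        raise CorpusError("corpus must contain both classes")
    if len(pos) > len(neg):
        return neg, pos
    return pos, neg


def subset_seed(seed: int, subset_index: int) -> int:
    """Stable per-subset seed derivation (kept below 2**31)."""
    return (seed + subset_index) % (2**31 - 1)


@dataclass
class BalancedSubset:
    """Index set for one balanced sub-dataset D_p."""

    subset_index: int
    minority_ids: list[str]
    majority_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.minority_ids) != len(self.majority_ids):
            raise CorpusError(
                f"subset {self.subset_index}: {len(self.minority_ids)} minority vs "
                f"{len(self.majority_ids)} majority users (must be balanced)"
            )

    @property
    def user_ids(self) -> list[str]:
        return list(self.minority_ids) + list(self.majority_ids)

    def view(self, corpus: Corpus) -> Corpus:
        return corpus.subset(self.user_ids, name=f"{corpus.name}:D{self.subset_index}")


@dataclass
class PartitionPlan:
    """The full set of balanced subsets built from one training corpus."""

    subsets: list[BalancedSubset]
    seed: int
    strategy: str

    @property
    def n(self) -> int:
        return len(self.subsets)

    def majority_coverage(self) -> set[str]:
        out: set[str] = set()
        for s in self.subsets:
            out.update(s.majority_ids)
        return out

    def to_json(self, path: str | Path) -> None:
        data = {
            "seed": self.seed,
            "strategy": self.strategy,
            "subsets": [
                {
                    "subset_index": s.subset_index,
                    "minority_ids": s.minority_ids,
                    "majority_ids": s.majority_ids,
                }
                for s in self.subsets
            ],
        }
        Path(path).write_text(json.dumps(data, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "PartitionPlan":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        subsets = [
            BalancedSubset(s["subset_index"], s["minority_ids"], s["majority_ids"])
            for s in data["subsets"]
        ]
        return cls(subsets, seed=data["seed"], strategy=data["strategy"])


def build_partition_plan(
    train_corpus: Corpus,
    n: int = 3,
    seed: int = 0,
    strategy: str = "independent_sample",
) -> PartitionPlan:
    """Divide an imbalanced training corpus into n balanced subsets.

    Every subset contains all minority users; majority membership follows
    the chosen strategy.  Deterministic given ``seed``.
    """
    if n < 1:
        raise CorpusError(f"n must be >= 1, got {n}")
    if strategy not in STRATEGIES:
        raise CorpusError(f"unknown strategy {strategy!r}")
    minority, majority = _classes(train_corpus)
    k = len(minority)

    subsets: list[BalancedSubset] = []
    if strategy == "independent_sample":
        for p in range(1, n + 1):
            rng = np.random.default_rng(subset_seed(seed, p))
            sample = list(rng.choice(majority, size=k, replace=False))
            subsets.append(BalancedSubset(p, list(minority), sample))
    else:  # disjoint_cycle
        rng = np.random.default_rng(seed)
        picks: list[list[str]] = [[] for _ in range(n)]
        members: list[set[str]] = [set() for _ in range(n)]
        cursor = 0
        while any(len(s) < k for s in picks):
            placed = False
            for uid in rng.permutation(majority):
                if all(len(s) >= k for s in picks):
                    break
                for step in range(n):
                    q = (cursor + step) % n
                    if len(picks[q]) < k and uid not in members[q]:
                        picks[q].append(str(uid))
                        members[q].add(str(uid))
                        cursor = (q + 1) % n
                        placed = True
                        break
            if not placed:
                raise CorpusError(
                    "cannot build balanced subsets: minority class larger than majority"
                )
        subsets = [BalancedSubset(p + 1, list(minority), picks[p]) for p in range(n)]
    return PartitionPlan(subsets, seed=seed, strategy=strategy)


def balanced_validation_view(
    val_corpus: Corpus, subset_index: int, seed: int
) -> BalancedSubset:
    """Balanced validation view for subset p, seeded as (seed + p)."""
    minority, majority = _classes(val_corpus)
    rng = np.random.default_rng(subset_seed(seed, subset_index))
    sample = list(rng.choice(majority, size=len(minority), replace=False))
    return BalancedSubset(subset_index, list(minority), sample)


def oversample_minority(train_corpus: Corpus, seed: int = 0) -> Corpus:
    """Duplicate uniformly sampled minority users until classes balance.

    Whole users are duplicated (with fresh ``#dupK`` id suffixes), never
    individual posts: the classification unit is the user.
    """
    minority, majority = _classes(train_corpus)
    deficit = len(majority) - len(minority)
    rng = np.random.default_rng(seed)
    extra = [str(u) for u in rng.choice(minority, size=deficit, replace=True)]
    ids = [u.user_id for u in train_corpus.users] + extra
    return train_corpus.subset(ids, name=f"{train_corpus.name}:oversampled")


def undersample_majority(train_corpus: Corpus, seed: int = 0) -> Corpus:
    """Retain a uniform majority sample equal in size to the minority class."""
    minority, majority = _classes(train_corpus)
    rng = np.random.default_rng(seed)
    keep = set(str(u) for u in rng.choice(majority, size=len(minority), replace=False))
    keep.update(minority)
    users = [u for u in train_corpus.users if u.user_id in keep]
    return Corpus(users, name=f"{train_corpus.name}:undersampled")
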