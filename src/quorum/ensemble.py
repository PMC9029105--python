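"""Two-level hierarchical majority-vote ensemble.

An n×m grid of base-classifier votes (n balanced sub-datasets, m
architectures per sub-dataset) is reduced in two stages: a majority vote
within each sub-dataset row gives a row verdict, and a majority vote over
the n row verdicts gives the final label.  The key combinatorial property,
verified exhaustively in the tests, is that the hierarchical reduction can
return the correct label with fewer than half the base classifiers correct
(e.g. 4 of 9 arranged 2+2+0), which a single flat majority over all n·m
votes never can.

Votes are hard labels (0/1, 1 = positive class).  The ensemble operation is
hard majority voting with a configurable tie rule; at the default odd
n = m = 3 ties cannot occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus, POSITIVE_LABEL, NEGATIVE_LABEL

TIE_RULES = ("positive", "negative")


@dataclass
class EnsembleConfig:
    """Shape and tie policy of the vote grid."""

    n_subsets: int = 3
    m_models: int = 3
    tie_rule: str = "positive"
    vote_kind: str = "hard"

    def __post_init__(self) -> None:
        if self.n_subsets < 1 or self.m_models < 1:
            raise ValueError("n_subsets and m_models must be >= 1")
        if self.tie_rule not in TIE_RULES:
            raise ValueError(f"tie_rule must be one of {TIE_RULES}")
        if self.vote_kind != "hard":
            raise ValueError("only hard voting is implemented")


@dataclass
class VoteMatrix:
    """All Eq-level intermediates for one user: r_pq grid, row verdicts r_p,
    final verdict r."""

    user_id: str
    votes: np.ndarray  # (n, m) ints in {0, 1}
    first_level: np.ndarray  # (n,)
    final: int
    true_label: int | None = None

    def __post_init__(self) -> None:
        self.votes = np.asarray(self.votes, dtype=np.int64)
        self.first_level = np.asarray(self.first_level, dtype=np.int64)


def majority_vote(labels: Sequence[int], tie_rule: str = "positive") -> int:
    """The strictly more frequent binary label; ties resolve per tie_rule."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("cannot take a majority of zero votes")
    ones = int(labels.sum())
    zeros = labels.size - ones
    if ones > zeros:
        return 1
    if zeros > ones:
        return 0
    return 1 if tie_rule == "positive" else 0


def _vote_axis(votes: np.ndarray, axis: int, tie_rule: str) -> np.ndarray:
    """Vectorised majority along one axis of a 0/1 array."""
    ones = votes.sum(axis=axis)
    total = votes.shape[axis]
    out = np.where(2 * ones > total, 1, 0)
    if total % 2 == 0:
        tie = 2 * ones == total
        out = np.where(tie, 1 if tie_rule == "positive" else 0, out)
    return out.astype(np.int64)


def hierarchical_predict(
    votes: np.ndarray | Sequence[Sequence[int]],
    config: EnsembleConfig | None = None,
    user_id: str = "",
    true_label: int | None = None,
) -> VoteMatrix:
    """Reduce an n×m vote grid in two stages of majority voting."""
    votes = np.asarray(votes, dtype=np.int64)
    if votes.ndim != 2:
        raise ValueError(f"vote grid must be 2-D, got shape {votes.shape}")
    config = config or EnsembleConfig(n_subsets=votes.shape[0], m_models=votes.shape[1])
    if votes.shape != (config.n_subsets, config.m_models):
        raise ValueError(
            f"grid shape {votes.shape} does not match config "
            f"({config.n_subsets}, {config.m_models})"
        )
    first = _vote_axis(votes, axis=1, tie_rule=config.tie_rule)
    final = majority_vote(first, config.tie_rule)
    return VoteMatrix(user_id, votes, first, final, true_label)


def flat_ensemble_oracle(
    votes: np.ndarray | Sequence[Sequence[int]], tie_rule: str = "positive"
) -> int:
    """Classical single-stage majority over all n·m votes (reference)."""
    votes = np.asarray(votes, dtype=np.int64)
    return majority_vote(votes.reshape(-1), tie_rule)


def vote_pattern_census(n: int, m: int, tie_rule: str = "positive") -> pd.DataFrame:
    """Exhaustive correctness census over all 2^(n·m) vote patterns.

    Taking the true label to be 1, enumerates every placement of correct
    (=1) votes on the n×m grid and tabulates, for each count k of correct
    classifiers, how many placements the hierarchical and the flat
    reductions each decide correctly.  The frame carries ``min_k_hier`` and
    ``min_k_flat`` attributes: the smallest k for which each reduction can
    be correct.
    """
    size = n * m
    if size > 20:
        raise ValueError(f"census bound exceeded: n*m = {size} > 20")
    ids = np.arange(2 ** size, dtype=np.int64)
    bits = (ids[:, None] >> np.arange(size)[None, :]) & 1  # (2^nm, nm)
    grids = bits.reshape(-1, n, m)
    k = bits.sum(axis=1)
    first = _vote_axis(grids, axis=2, tie_rule=tie_rule)  # (2^nm, n)
    hier = _vote_axis(first, axis=1, tie_rule=tie_rule)
    flat = _vote_axis(bits, axis=1, tie_rule=tie_rule)
    rows = []
    for kk in range(size + 1):
        sel = k == kk
        rows.append({
            "k": kk,
            "n_placements": int(sel.sum()),
            "n_hier_correct": int((hier[sel] == 1).sum()),
            "n_flat_correct": int((flat[sel] == 1).sum()),
        })
    table = pd.DataFrame(rows)
    table.attrs["min_k_hier"] = int(table.loc[table.n_hier_correct > 0, "k"].min())
    table.attrs["min_k_flat"] = int(table.loc[table.n_flat_correct > 0, "k"].min())
    return table


def census_to_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def predict_corpus(
    classifier_grid: Sequence[Sequence],
    corpus: Corpus,
    config: EnsembleConfig | None = None,
) -> list[VoteMatrix]:
    """Fill the vote grid for every user of a corpus and reduce it.

    ``classifier_grid`` is an n×m nested sequence of trained classifiers
    (row p = the m models trained on sub-dataset D_p).  Each classifier
    predicts the whole corpus in one batch; the per-user grids are then
    reduced hierarchically.
    """
    n = len(classifier_grid)
    if n == 0 or any(clf is None for row in classifier_grid for clf in row):
        raise ValueError("classifier grid has missing entries")
    m = len(classifier_grid[0])
    if any(len(row) != m for row in classifier_grid):
        raise ValueError("classifier grid is ragged")
    config = config or EnsembleConfig(n_subsets=n, m_models=m)

    users = corpus.users
    all_votes = np.zeros((len(users), n, m), dtype=np.int64)
    for p, row in enumerate(classifier_grid):
        for q, clf in enumerate(row):
            all_votes[:, p, q] = clf.predict_users(users)
    out = []
    for i, u in enumerate(users):
        truth = None if u.label is None else int(u.is_positive)
        out.append(hierarchical_predict(all_votes[i], config, u.user_id, truth))
    return out


def votes_to_frame(matrices: Sequence[VoteMatrix]) -> pd.DataFrame:
    """Bit-exact replay table: user_id, true label, every r_pq, r_p, final."""
    rows = []
    for vm in matrices:
        n, m = vm.votes.shape
        row: dict[str, object] = {"user_id": vm.user_id, "true_label": vm.true_label}
        for p in range(n):
            for q in range(m):
                row[f"r_{p + 1}{q + 1}"] = int(vm.votes[p, q])
        for p in range(n):
            row[f"r_{p + 1}"] = int(vm.first_level[p])
        row["final"] = vm.final
        rows.append(row)
    return pd.DataFrame(rows)


def label_of(vote: int) -> str:
    return POSITIVE_LABEL if vote == 1 else NEGATIVE_LABEL
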