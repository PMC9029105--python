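"""Model/Results interface to the hierarchical vote ensemble.

:class:`HierarchicalVoteEnsemble` is built from a corpus plus the design
choices (number of balanced subsets n, the m base architectures, the
sampling strategy); :meth:`fit` trains the full n×m classifier grid and
returns an :class:`EnsembleResults` carrying the trained grid, per-classifier
validation scores, and prediction/evaluation/summary methods, in the spirit
of the model–results split used by statistical modelling packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classifiers import (
    NEURAL_ARCHITECTURES,
    TrainConfig,
    TrainedClassifier,
    train_classifier,
)
from .corpus import Corpus, SplitAssignment, read_corpus, stratified_split
from .encoding import Tokenizer, Vocabulary, build_vocabulary, whitespace_tokenizer
from .ensemble import (
    EnsembleConfig,
    VoteMatrix,
    label_of,
    predict_corpus,
    votes_to_frame,
)
from .evaluation import MetricsReport, compute_metrics
from .sampling import PartitionPlan, balanced_validation_view, build_partition_plan


def derive_seed(seed: int, p: int, q: int) -> int:
    """Stable per-classifier seed (kept below 2**31)."""
    return (seed * 10_007 + p * 101 + q) % (2**31 - 1)


class HierarchicalVoteEnsemble:
    """Two-level majority-vote ensemble over balanced sub-datasets.

    Parameters
    ----------
    corpus : Corpus
        Labelled user corpus (already cleaned/masked as desired).
    split : SplitAssignment, optional
        Train/val/test assignment; if omitted, a stratified split with
        ``ratios`` is drawn inside :meth:`fit` from its seed.
    n_subsets : int
        Number of balanced sub-datasets n (rows of the vote grid).
    architectures : sequence of str
        Base architectures per subset (columns of the vote grid).
    strategy : str
        ``independent_sample`` or ``disjoint_cycle`` majority sampling.
    base_config : TrainConfig, optional
        Template hyperparameters; architecture and seed are overridden per
        grid cell.
    """

    def __init__(
        self,
        corpus: Corpus,
        split: SplitAssignment | None = None,
        *,
        n_subsets: int = 3,
        architectures: Sequence[str] = NEURAL_ARCHITECTURES,
        strategy: str = "independent_sample",
        base_config: TrainConfig | None = None,
        ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
        tie_rule: str = "positive",
        min_frequency: int = 1,
        tokenizer: Tokenizer = whitespace_tokenizer,
    ) -> None:
        self.corpus = corpus
        self.split = split
        self.n_subsets = n_subsets
        self.architectures = tuple(architectures)
        self.strategy = strategy
        self.base_config = base_config or TrainConfig()
        self.ratios = ratios
        self.tie_rule = tie_rule
        self.min_frequency = min_frequency
        self.tokenizer = tokenizer

    @classmethod
    def from_jsonl(cls, path: str | Path, **kwargs) -> "HierarchicalVoteEnsemble":
        return cls(read_corpus(path), **kwargs)

    @property
    def m_models(self) -> int:
        return len(self.architectures)

    def fit(self, seed: int = 0) -> "EnsembleResults":
        """Split, build balanced subsets, train the n×m grid."""
        split = self.split or stratified_split(self.corpus, self.ratios, seed)
        train_c = split.partition_corpus(self.corpus, "train")
        val_c = split.partition_corpus(self.corpus, "val")
        plan = build_partition_plan(train_c, self.n_subsets, seed, self.strategy)
        vocab = build_vocabulary(train_c, self.min_frequency, self.tokenizer)

        grid: list[list[TrainedClassifier]] = []
        for p in range(1, self.n_subsets + 1):
            subset = plan.subsets[p - 1]
            val_view = balanced_validation_view(val_c, p, seed)
            train_users = subset.view(train_c).users
            val_users = val_view.view(val_c).users
            row = []
            for q, arch in enumerate(self.architectures, start=1):
                cfg = self.base_config.replace(
                    architecture=arch, seed=derive_seed(seed, p, q))
                row.append(train_classifier(train_users, val_users, cfg,
                                            vocabulary=vocab, tokenizer=self.tokenizer))
            grid.append(row)
        return EnsembleResults(self, grid, plan, vocab, split, seed)


@dataclass
class EnsembleResults:
    """Fitted ensemble: the trained grid plus prediction and reporting."""

    model: HierarchicalVoteEnsemble
    classifier_grid: list[list[TrainedClassifier]]
    plan: PartitionPlan
    vocabulary: Vocabulary
    split: SplitAssignment
    seed: int
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def ensemble_config(self) -> EnsembleConfig:
        return EnsembleConfig(
            n_subsets=self.model.n_subsets,
            m_models=self.model.m_models,
            tie_rule=self.model.tie_rule,
        )

    def validation_scores(self) -> pd.DataFrame:
        rows = []
        for p, row in enumerate(self.classifier_grid, start=1):
            for q, clf in enumerate(row, start=1):
                rows.append({"subset": p, "model": q,
                             "architecture": clf.architecture,
                             "validation_f1": clf.validation_f1})
        return pd.DataFrame(rows)

    def test_corpus(self) -> Corpus:
        return self.split.partition_corpus(self.model.corpus, "test")

    def predict(self, corpus: Corpus | None = None) -> list[VoteMatrix]:
        """Per-user vote matrices for ``corpus`` (default: test partition)."""
        corpus = corpus if corpus is not None else self.test_corpus()
        return predict_corpus(self.classifier_grid, corpus, self.ensemble_config)

    def predict_labels(self, corpus: Corpus | None = None) -> dict[str, str]:
        return {vm.user_id: label_of(vm.final) for vm in self.predict(corpus)}

    def predictions_frame(self, corpus: Corpus | None = None) -> pd.DataFrame:
        return votes_to_frame(self.predict(corpus))

    def evaluate(self, corpus: Corpus | None = None) -> MetricsReport:
        """Confusion-matrix metrics of the final (second-level) labels."""
        matrices = self.predict(corpus)
        pairs = [(vm.true_label, vm.final) for vm in matrices]
        if any(t is None for t, _ in pairs):
            raise ValueError("evaluation requires labelled users")
        return compute_metrics(pairs)

    def summary(self) -> str:
        """Human-readable fit report (validation grid + test metrics)."""
        m = self.model
        lines = [
            "Hierarchical Vote Ensemble Results",
            "=" * 50,
            f"corpus:          {m.corpus.name or '<unnamed>'} "
            f"({len(m.corpus)} users: {m.corpus.n_positive} pos / {m.corpus.n_negative} neg)",
            f"grid:            n={m.n_subsets} subsets x m={m.m_models} models "
            f"({', '.join(m.architectures)})",
            f"strategy:        {m.strategy}   seed: {self.seed}",
            f"vocabulary:      {len(self.vocabulary)} tokens",
            "-" * 50,
            "validation F1 per base classifier:",
        ]
        vs = self.validation_scores()
        vs["column"] = [f"m{q}:{a}" for q, a in zip(vs.model, vs.architecture)]
        grid = vs.pivot(index="subset", columns="column", values="validation_f1")
        lines.append(grid.round(4).to_string())
        try:
            rep = self.evaluate()
        except ValueError:
            rep = None
        if rep is not None:
            lines += [
                "-" * 50,
                f"test users:      {rep.n}",
                f"accuracy:        {rep.accuracy:.4f}",
                f"precision:       {rep.precision:.4f}",
                f"recall:          {rep.recall:.4f}",
                f"F1 (positive):   {rep.f1:.4f}",
            ]
        return "\n".join(lines)
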