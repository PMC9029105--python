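"""End-to-end experiment orchestration with replayable manifests.

One experiment executes: clean → (optional) sentence-level mask → stratified
split → balanced partition plan → train the n×m classifier grid →
hierarchical prediction → evaluation, together with the requested baselines:

``single``
    each architecture trained once on the full imbalanced training set;
    the best by validation F1 is the baseline.
``oversample`` / ``undersample``
    the baseline architecture retrained on a resampled (balanced) training
    set.
``hierarchical``
    the two-level vote ensemble itself.

All outputs land under a fixed workdir layout (``corpora/``, ``plans/``,
``models/``, ``predictions/``, ``reports/``, ``manifest.json``); replaying a
manifest reproduces every prediction file exactly, because every random
choice derives from the config seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .classifiers import (
    NEURAL_ARCHITECTURES,
    TrainConfig,
    TrainedClassifier,
    train_classifier,
)
from .corpus import Corpus, POSITIVE_LABEL, read_corpus, stratified_split, write_corpus
from .ensemble import votes_to_frame
from .evaluation import ComparisonTable, compare_methods, compute_metrics
from .model import HierarchicalVoteEnsemble, derive_seed
from .preprocessing import CleaningConfig, MaskConfig, apply_sentence_mask, clean_corpus
from .sampling import oversample_minority, undersample_majority

log = logging.getLogger("quorum")

BASELINES = ("single", "oversample", "undersample", "hierarchical")


@dataclass
class ExperimentConfig:
    """Everything needed to replay one experiment bit-for-bit."""

    corpus_path: str
    workdir: str
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    n_subsets: int = 3
    architectures: tuple[str, ...] = NEURAL_ARCHITECTURES
    strategy: str = "independent_sample"
    mask: bool = False
    clean: bool = True
    baselines: tuple[str, ...] = BASELINES
    min_posts_per_user: int = 3
    train_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.architectures = tuple(self.architectures)
        self.baselines = tuple(self.baselines)
        self.ratios = tuple(self.ratios)
        unknown = set(self.baselines) - set(BASELINES)
        if unknown:
            raise ValueError(f"unknown baselines: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class ExperimentReport:
    """All evaluated runs of one experiment plus the comparison table."""

    config: ExperimentConfig
    comparison: ComparisonTable
    predictions: dict[str, list[tuple[str, str, str]]]  # method -> (uid, true, pred)
    validation_f1: dict[str, float]
    best_single: str
    workdir: Path

    def metrics(self, method: str):
        return compute_metrics([(t, p) for _, t, p in self.predictions[method]])


def _stage(name: str, t0: float, n_in: int | None = None, n_out: int | None = None) -> None:
    extra = ""
    if n_in is not None:
        extra = f" in={n_in} out={n_out}"
    log.info("stage=%s wall=%.2fs%s", name, time.time() - t0, extra)


def _single_prediction(clf: TrainedClassifier, corpus: Corpus) -> list[tuple[str, str, str]]:
    preds = clf.predict_users(corpus.users)
    return [
        (u.user_id, u.label, POSITIVE_LABEL if p == 1 else "non_suicidal")
        for u, p in zip(corpus.users, preds)
    ]


def run_experiment(config: ExperimentConfig, corpus: Corpus | None = None) -> ExperimentReport:
    """Execute the full protocol described in the module docstring.

    ``corpus`` may be passed directly (e.g. freshly generated); otherwise
    it is read from ``config.corpus_path``.
    """
    workdir = Path(config.workdir)
    for sub in ("corpora", "plans", "models", "predictions", "reports"):
        (workdir / sub).mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    if corpus is None:
        corpus = read_corpus(config.corpus_path)
    n_raw = len(corpus)

    if config.clean:
        cleaning = CleaningConfig(min_posts_per_user=config.min_posts_per_user)
        corpus, tally = clean_corpus(corpus, cleaning)
        tally.to_tsv(workdir / "reports" / "cleaning_tally.tsv")
    if config.mask:
        corpus, mask_tally = apply_sentence_mask(corpus, MaskConfig())
        mask_tally.to_tsv(workdir / "reports" / "mask_tally.tsv")
    write_corpus(corpus, workdir / "corpora" / "prepared.jsonl")
    _stage("prepare", t0, n_raw, len(corpus))

    split = stratified_split(corpus, config.ratios, config.seed)
    split.to_tsv(workdir / "plans" / "split.tsv")
    train_c = split.partition_corpus(corpus, "train")
    val_c = split.partition_corpus(corpus, "val")
    test_c = split.partition_corpus(corpus, "test")

    base_cfg = TrainConfig(**config.train_overrides)
    predictions: dict[str, list[tuple[str, str, str]]] = {}
    validation_f1: dict[str, float] = {}

    # --- single-architecture baselines on the full imbalanced training set
    singles: dict[str, TrainedClassifier] = {}
    if {"single", "oversample", "undersample"} & set(config.baselines):
        for q, arch in enumerate(config.architectures, start=1):
            t1 = time.time()
            cfg = base_cfg.replace(architecture=arch, seed=derive_seed(config.seed, 0, q))
            clf = train_classifier(train_c.users, val_c.users, cfg)
            singles[arch] = clf
            validation_f1[f"single_{arch}"] = clf.validation_f1
            clf.save(workdir / "models" / f"single_{arch}")
            _stage(f"train_single_{arch}", t1, len(train_c))
    best_single = max(singles, key=lambda a: singles[a].validation_f1) if singles else ""

    if "single" in config.baselines:
        predictions["single"] = _single_prediction(singles[best_single], test_c)

    if "oversample" in config.baselines:
        t1 = time.time()
        over = oversample_minority(train_c, seed=config.seed)
        cfg = singles[best_single].config.replace(seed=derive_seed(config.seed, 98, 1))
        clf = train_classifier(over.users, val_c.users, cfg)
        validation_f1["oversample"] = clf.validation_f1
        predictions["oversample"] = _single_prediction(clf, test_c)
        _stage("train_oversample", t1, len(over))

    if "undersample" in config.baselines:
        t1 = time.time()
        under = undersample_majority(train_c, seed=config.seed)
        cfg = singles[best_single].config.replace(seed=derive_seed(config.seed, 99, 1))
        clf = train_classifier(under.users, val_c.users, cfg)
        validation_f1["undersample"] = clf.validation_f1
        predictions["undersample"] = _single_prediction(clf, test_c)
        _stage("train_undersample", t1, len(under))

    if "hierarchical" in config.baselines:
        t1 = time.time()
        model = HierarchicalVoteEnsemble(
            corpus, split,
            n_subsets=config.n_subsets,
            architectures=config.architectures,
            strategy=config.strategy,
            base_config=base_cfg,
            ratios=config.ratios,
        )
        results = model.fit(seed=config.seed)
        results.plan.to_json(workdir / "plans" / "partition_plan.json")
        for p, row in enumerate(results.classifier_grid, start=1):
            for clf in row:
                clf.save(workdir / "models" / f"subset{p}_{clf.architecture}")
        matrices = results.predict(test_c)
        votes_to_frame(matrices).to_csv(
            workdir / "predictions" / "hierarchical_votes.tsv", sep="\t", index=False)
        predictions["hierarchical"] = [
            (vm.user_id, test_c.by_id(vm.user_id).label,
             POSITIVE_LABEL if vm.final == 1 else "non_suicidal")
            for vm in matrices
        ]
        for _, r in results.validation_scores().iterrows():
            validation_f1[f"subset{r.subset}_{r.architecture}"] = r.validation_f1
        _stage("train_hierarchical", t1, len(train_c))

    for method, rows in predictions.items():
        pd.DataFrame(rows, columns=["user_id", "true_label", "predicted_label"]).to_csv(
            workdir / "predictions" / f"{method}.tsv", sep="\t", index=False)

    comparison = compare_methods(
        {m: [(t, p) for _, t, p in rows] for m, rows in predictions.items()})
    comparison.to_tsv(workdir / "reports" / "comparison")

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "best_single": best_single,
        "validation_f1": validation_f1,
        "n_users_prepared": len(corpus),
    }
    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=1),
                                           encoding="utf-8")
    _stage("experiment", t0, n_raw, len(corpus))
    return ExperimentReport(config, comparison, predictions, validation_f1,
                            best_single, workdir)


def replay_manifest(path: str | Path) -> ExperimentReport:
    """Re-run an experiment from its manifest (bit-for-bit reproduction)."""
    manifest = json.loads(Path(path).read_text(encoding="utf-8"))
    return run_experiment(ExperimentConfig(**manifest["config"]))
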