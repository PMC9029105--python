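"""Generator determinism, class structure, hidden-signal construction,
and the dirty-corpus injection ledger against cleaning tallies."""

import re
from collections import Counter

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from quorum.preprocessing import CleaningConfig, apply_sentence_mask, clean_corpus
from quorum.synthetic import (
    GeneratorConfig,
    GroundTruth,
    NoiseSpec,
    generate_corpus,
    generate_dirty_corpus,
)

SMALL = dict(n_positive=25, n_negative=40,
             posts_per_user_mean_positive=4, posts_per_user_mean_negative=6,
             post_length_mean_positive=8, post_length_mean_negative=8)


class TestGenerateCorpus:
    def test_deterministic_given_config(self, tmp_path):
        cfg = GeneratorConfig(**SMALL, seed=7)
        a, ta = generate_corpus(cfg)
        b, tb = generate_corpus(cfg)
        assert [u.user_id for u in a.users] == [u.user_id for u in b.users]
        assert all(x.posts == y.posts for x, y in zip(a.users, b.users))
        assert ta.hidden_ids() == tb.hidden_ids()
        # and byte-identical on disk
        from quorum.corpus import write_corpus
        pa, pb = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        write_corpus(a, pa), write_corpus(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_exact_class_prevalence(self):
        corpus, _ = generate_corpus(GeneratorConfig(**SMALL, seed=1))
        assert corpus.n_positive == 25 and corpus.n_negative == 40

    def test_negative_users_never_post_in_tree_hole(self):
        corpus, _ = generate_corpus(GeneratorConfig(**SMALL, seed=2))
        for u in corpus.negative_users():
            assert all(p.source == "ordinary" for p in u.posts)

    def test_every_positive_user_has_a_tree_hole_post(self):
        corpus, _ = generate_corpus(GeneratorConfig(**SMALL, seed=3))
        for u in corpus.positive_users():
            assert any(p.source == "tree_hole" for p in u.posts)

    def test_hidden_users_signal_only_in_tree_hole(self):
        cfg = GeneratorConfig(**SMALL, hidden_fraction=0.4, seed=4)
        corpus, truth = generate_corpus(cfg)
        assert len(truth.hidden_ids()) == round(0.4 * 25)
        for uid in truth.hidden_ids():
            user = corpus.by_id(uid)
            for j in truth.users[uid].signal_post_indices:
                assert user.posts[j].source == "tree_hole"
            # ordinary posts carry no positive/tree-hole signal tokens
            for p in user.posts:
                if p.source == "ordinary":
                    assert not re.search(r"\b(pos|th)\d+", p.text)

    def test_masked_hidden_users_indistinguishable_from_negatives(self):
        """With hidden_fraction=1, masking leaves positive users' token
        distribution statistically identical to negatives' (chi-square on
        pooled token counts, median p over 10 seeds above alpha=0.01)."""
        pvals = []
        for seed in range(10):
            # ambiguous negatives off: the check isolates the hidden-user
            # construction, which matches the typical negative profile
            cfg = GeneratorConfig(**SMALL, hidden_fraction=1.0,
                                  ambiguous_negative_fraction=0.0, seed=seed)
            corpus, _ = generate_corpus(cfg)
            masked, _ = apply_sentence_mask(corpus)
            pos = Counter(t for u in masked.positive_users()
                          for p in u.posts for t in p.text.split())
            neg = Counter(t for u in masked.negative_users()
                          for p in u.posts for t in p.text.split())
            toks = sorted(set(pos) | set(neg))
            table = np.array([[pos.get(t, 0) + 1 for t in toks],
                              [neg.get(t, 0) + 1 for t in toks]])
            pvals.append(chi2_contingency(table)[1])
        assert np.median(pvals) > 0.01

    def test_zero_treehole_rate_makes_mask_noop_outside_forced_posts(self):
        """With no tree-hole posts at all (hidden off, rate 0 and forcing
        disabled via negative users), masking negatives changes nothing."""
        corpus, _ = generate_corpus(GeneratorConfig(**SMALL, seed=6,
                                                    treehole_post_rate=0.0))
        masked, _ = apply_sentence_mask(corpus)
        # negatives untouched; positives keep their single forced disclosure removed
        for u in masked.negative_users():
            assert u.posts == corpus.by_id(u.user_id).posts

    def test_ground_truth_round_trip(self, tmp_path):
        _, truth = generate_corpus(GeneratorConfig(**SMALL, seed=8))
        path = tmp_path / "truth.jsonl"
        truth.to_jsonl(path)
        back = GroundTruth.from_jsonl(path)
        assert back.users == truth.users

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(hidden_fraction=1.5)
        with pytest.raises(ValueError):
            GeneratorConfig(n_positive=0)


class TestDirtyCorpus:
    def test_zero_noise_equals_clean_generation(self):
        cfg = GeneratorConfig(**SMALL, seed=9)
        zero = NoiseSpec(**{f: 0.0 for f in NoiseSpec().__dataclass_fields__})
        dirty, ledger = generate_dirty_corpus(cfg, zero)
        base, _ = generate_corpus(cfg)
        assert all(a.posts == b.posts for a, b in zip(dirty.users, base.users))
        assert ledger.strips == {} and ledger.system_posts == 0

    def test_cleaning_tally_matches_injection_ledger(self):
        """Per-rule removal tallies equal the injection ledger exactly."""
        cfg = GeneratorConfig(**SMALL, seed=10)
        dirty, ledger = generate_dirty_corpus(cfg, NoiseSpec())
        cleaned, tally = clean_corpus(dirty, CleaningConfig(min_posts_per_user=1))
        for rule in ("url", "mention", "emoticon", "boilerplate",
                     "location", "supertopic"):
            assert tally.strips.get(rule, 0) == ledger.strips.get(rule, 0), rule
        assert tally.posts_removed.get("system", 0) == ledger.system_posts
        assert tally.posts_removed.get("empty_residue", 0) == ledger.url_only_posts

    def test_cleaned_dirty_corpus_has_no_residual_noise(self):
        dirty, _ = generate_dirty_corpus(GeneratorConfig(**SMALL, seed=11), NoiseSpec())
        cleaned, _ = clean_corpus(dirty, CleaningConfig(min_posts_per_user=1))
        pattern = re.compile(r"(https?://|@\S|\[|#[^#]+#|sharing pictures|Beijing)")
        for u in cleaned.users:
            for p in u.posts:
                assert not pattern.search(p.text), p.text

    def test_system_post_injection_counted(self):
        spec = NoiseSpec(url_rate=0, mention_rate=0, emoticon_rate=0,
                         boilerplate_rate=0, location_rate=0, supertopic_rate=0,
                         system_post_rate=0.5, url_only_post_rate=0)
        dirty, ledger = generate_dirty_corpus(GeneratorConfig(**SMALL, seed=12), spec)
        n_system = sum(1 for u in dirty.users for p in u.posts if p.source == "system")
        assert n_system == ledger.system_posts > 0
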