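"""Cleaning pipeline rules, tallies, idempotence, and the sentence mask."""

import pytest
from hypothesis import given, settings, strategies as st

from quorum.corpus import Corpus, Post, UserRecord
from quorum.preprocessing import (
    CleaningConfig,
    MaskConfig,
    apply_sentence_mask,
    clean_corpus,
    clean_post,
)

CFG = CleaningConfig(min_posts_per_user=1)


class TestCleanPost:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("see this http://t.cn/abc @alice", "see this"),
            ("hello [笑] world", "hello world"),
            ("a #SuperTopic title# b", "a b"),
            ("visit Beijing today", "visit today"),
            ("sharing pictures", None),  # boilerplate-only -> empty residue
            ("http://t.cn/only", None),
            ("plain text stays", "plain text stays"),
            ("emoji 😀 gone", "emoji gone"),
        ],
    )
    def test_rules(self, text, expected):
        out = clean_post(Post(text, "ordinary"), CFG)
        if expected is None:
            assert out is None
        else:
            assert out.text == expected

    def test_system_post_removed(self):
        assert clean_post(Post("anything at all", "system"), CFG) is None

    def test_source_and_timestamp_preserved(self):
        p = Post("keep @me clean", "tree_hole", "2020-07-01")
        out = clean_post(p, CFG)
        assert (out.source, out.created_at) == ("tree_hole", "2020-07-01")

    @settings(max_examples=300, deadline=None)
    @given(st.text(max_size=80), st.sampled_from(["tree_hole", "ordinary"]))
    def test_idempotent(self, text, source):
        """clean(clean(p)) == clean(p) for arbitrary input text."""
        once = clean_post(Post(text, source), CFG)
        if once is not None:
            twice = clean_post(once, CFG)
            assert twice is not None and twice.text == once.text

    def test_idempotent_on_adversarial_overlap(self):
        # substring removal that would regenerate a match if applied once
        cfg = CleaningConfig(boilerplate_phrases=("abab",), min_posts_per_user=1)
        out = clean_post(Post("ababab x", "ordinary"), cfg)
        assert out is not None and "abab" not in out.text


class TestCleanCorpus:
    def test_hand_counted_tally(self):
        """10 posts: 2 system + 1 URL-only removed; 7 survive."""
        posts = (
            [Post("ok text %d" % i) for i in range(6)]
            + [Post("auto", "system"), Post("auto2", "system")]
            + [Post("http://t.cn/x")]
            + [Post("fine with @tag")]
        )
        corpus = Corpus([UserRecord("u", posts, "suicidal")])
        cleaned, tally = clean_corpus(corpus, CFG)
        assert tally.posts_removed == {"system": 2, "empty_residue": 1}
        assert cleaned.users[0].n_posts == 7

    def test_clean_corpus_fixed_point(self, tiny_corpus):
        cleaned, tally = clean_corpus(tiny_corpus, CFG)
        assert not tally.posts_removed and not tally.users_removed
        again, tally2 = clean_corpus(cleaned, CFG)
        assert [u.posts for u in again.users] == [u.posts for u in cleaned.users]

    def test_min_posts_drops_user(self):
        corpus = Corpus([
            UserRecord("few", [Post("one"), Post("two")], "suicidal"),
            UserRecord("many", [Post(f"t {i}") for i in range(4)], "suicidal"),
        ])
        cleaned, tally = clean_corpus(corpus, CleaningConfig(min_posts_per_user=3))
        assert [u.user_id for u in cleaned.users] == ["many"]
        assert tally.users_removed == {"min_posts": 1}

    def test_user_emptied_by_cleaning_dropped(self):
        corpus = Corpus([UserRecord("u", [Post("x", "system")], "suicidal")])
        cleaned, _ = clean_corpus(corpus, CFG)
        assert len(cleaned) == 0


class TestSentenceMask:
    def test_tree_hole_posts_deleted_ordinary_kept(self):
        """A user with one overt tree-hole disclosure keeps only the
        ordinary timeline after masking."""
        user = UserRecord("u", [
            Post("Loop this song infinitely, crying while listening.", "ordinary"),
            Post("I want to see my blood pouring out from the cut arteries", "tree_hole"),
            Post("He laughs really well.", "ordinary"),
        ], "suicidal")
        masked, tally = apply_sentence_mask(Corpus([user]))
        texts = [p.text for p in masked.users[0].posts]
        assert texts == ["Loop this song infinitely, crying while listening.",
                         "He laughs really well."]
        assert tally.posts_removed == {"masked_source": 1}

    def test_no_tree_hole_identity(self, tiny_corpus):
        no_th = Corpus([UserRecord(u.user_id,
                                   [p for p in u.posts if p.source != "tree_hole"],
                                   u.label) for u in tiny_corpus.users])
        masked, tally = apply_sentence_mask(no_th)
        assert [u.posts for u in masked.users] == [u.posts for u in no_th.users]

    def test_all_tree_hole_user_dropped_and_reported(self):
        corpus = Corpus([UserRecord("u", [Post("a", "tree_hole"),
                                          Post("b", "tree_hole")], "suicidal")])
        masked, tally = apply_sentence_mask(corpus)
        assert len(masked) == 0
        assert tally.users_removed == {"masked_source": 1}

    def test_never_increases_counts_and_idempotent(self, tiny_corpus):
        masked, _ = apply_sentence_mask(tiny_corpus)
        for u in masked.users:
            assert u.n_posts <= tiny_corpus.by_id(u.user_id).n_posts
        twice, tally2 = apply_sentence_mask(masked)
        assert [u.posts for u in twice.users] == [u.posts for u in masked.users]
        assert not tally2.users_removed

    def test_commutes_with_cleaning_away_from_threshold(self, tiny_corpus):
        cfg = CleaningConfig(min_posts_per_user=1)
        a, _ = clean_corpus(apply_sentence_mask(tiny_corpus)[0], cfg)
        b, _ = apply_sentence_mask(clean_corpus(tiny_corpus, cfg)[0])
        assert [(u.user_id, u.posts) for u in a.users] == \
               [(u.user_id, u.posts) for u in b.users]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            MaskConfig(frozenset())
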