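import numpy as np
import pytest

from quorum.corpus import Corpus, Post, UserRecord


def make_user(uid: str, texts, label="non_suicidal", sources=None):
    sources = sources or ["ordinary"] * len(texts)
    return UserRecord(uid, [Post(t, s) for t, s in zip(texts, sources)], label)


@pytest.fixture
def tiny_corpus():
    """Four users, two per class, with provenance-tagged posts."""
    return Corpus(
        [
            make_user("p1", ["die pain cry", "nothing alive", "want not"],
                      "suicidal", ["tree_hole", "ordinary", "ordinary"]),
            make_user("p2", ["blood pouring out", "loop this song"],
                      "suicidal", ["tree_hole", "ordinary"]),
            make_user("n1", ["laugh cute buy", "good-looking today", "feel like"]),
            make_user("n2", ["see cry cannot", "cute today"]),
        ],
        name="tiny",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
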