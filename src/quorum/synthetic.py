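"""Synthetic imbalanced, provenance-tagged corpora with known ground truth.

The generator emulates the statistical structure the method assumes, at
desk scale, with a four-block unigram vocabulary:

* a *shared* block used by everyone,
* a *positive-signal* block mixed into the ordinary posts of (most)
  positive users,
* a *tree-hole-signal* block mixed into tree-hole-tagged posts of positive
  users at its own (high) mixture weight — disclosures in the tree hole are
  overt, unlike the subtle ordinary-timeline signal — and
* a *negative-signal* block mixed into negative users' posts.

A configurable fraction of positive users are *hidden*: their ordinary
posts are drawn from exactly the negative users' distribution, and their
only class-indicative posts are tree-hole-tagged.  Deleting tree-hole posts
therefore makes hidden users indistinguishable from negatives by
construction, which is what gives the sentence-level mask its measurable
difficulty.

Class prevalence, per-user post counts and post lengths default to a
one-tenth scale of the corpus the design targets (160 positive vs 290
negative users; mean 8 vs 15 posts per user).  Everything is a pure
function of the config, including its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .corpus import Corpus, Post, UserRecord

_EPOCH = np.datetime64("2020-07-01")


@dataclass
class GeneratorConfig:
    """Study conditions for corpus generation (all counts are exact)."""

    n_positive: int = 160
    n_negative: int = 290
    posts_per_user_mean_positive: float = 8.0
    posts_per_user_mean_negative: float = 15.0
    post_length_mean_positive: float = 12.0
    post_length_mean_negative: float = 12.0
    vocab_shared: int = 400
    vocab_positive_signal: int = 30
    vocab_treehole_signal: int = 30
    vocab_negative_signal: int = 30
    signal_strength: float = 0.2
    treehole_signal_strength: float = 0.7
    hidden_fraction: float = 0.3
    treehole_post_rate: float = 0.3
    ambiguous_negative_fraction: float = 0.2
    ambiguous_signal_strength: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_positive", "n_negative", "vocab_shared",
                     "vocab_positive_signal", "vocab_treehole_signal",
                     "vocab_negative_signal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("signal_strength", "treehole_signal_strength",
                     "hidden_fraction", "treehole_post_rate",
                     "ambiguous_negative_fraction", "ambiguous_signal_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("posts_per_user_mean_positive", "posts_per_user_mean_negative",
                     "post_length_mean_positive", "post_length_mean_negative"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1), encoding="utf-8")


@dataclass
class UserTruth:
    label: str
    hidden: bool
    signal_post_indices: list[int]
    ambiguous: bool = False


@dataclass
class GroundTruth:
    """Per-user generation record enabling oracle checks of masking effects."""

    users: dict[str, UserTruth] = field(default_factory=dict)

    def hidden_ids(self) -> list[str]:
        return [uid for uid, t in self.users.items() if t.hidden]

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for uid, t in self.users.items():
                fh.write(json.dumps({"user_id": uid, **asdict(t)}) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "GroundTruth":
        users = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    obj = json.loads(line)
                    uid = obj.pop("user_id")
                    users[uid] = UserTruth(**obj)
        return cls(users)


def _blocks(config: GeneratorConfig) -> dict[str, list[str]]:
    return {
        "shared": [f"w{i}" for i in range(config.vocab_shared)],
        "pos": [f"pos{i}" for i in range(config.vocab_positive_signal)],
        "th": [f"th{i}" for i in range(config.vocab_treehole_signal)],
        "neg": [f"neg{i}" for i in range(config.vocab_negative_signal)],
    }


def _mix_post(rng: np.random.Generator, length: int, shared: list[str],
              signal: list[str] | None, strength: float) -> str:
    toks = []
    for _ in range(length):
        if signal is not None and rng.random() < strength:
            toks.append(signal[rng.integers(len(signal))])
        else:
            toks.append(shared[rng.integers(len(shared))])
    return " ".join(toks)


def _timestamp(rng: np.random.Generator) -> str:
    day = int(rng.integers(0, 365))
    return str(_EPOCH + np.timedelta64(day, "D"))


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Generate one corpus plus its ground truth; deterministic in the config.

    Per-user post counts and per-post token lengths are Poisson(mean)+1.
    Every positive user has at least one tree-hole post (mirroring
    annotation via tree-hole activity); negative users have none.
    """
    rng = np.random.default_rng(config.seed)
    blocks = _blocks(config)
    users: list[UserRecord] = []
    truth = GroundTruth()

    n_hidden = int(round(config.hidden_fraction * config.n_positive))
    hidden_flags = np.zeros(config.n_positive, dtype=bool)
    hidden_flags[rng.choice(config.n_positive, size=n_hidden, replace=False)] = True

    for i in range(config.n_positive):
        uid = f"pos_u{i:04d}"
        hidden = bool(hidden_flags[i])
        posts, signal_idx = [], []
        if hidden:
            # Hidden users must be indistinguishable from negatives once
            # their tree-hole posts are deleted, so their ordinary posts
            # follow the *negative* class in count, length and content;
            # tree-hole disclosures are added on top.
            n_posts = int(rng.poisson(config.posts_per_user_mean_negative)) + 1
            is_th = rng.random(n_posts) < config.treehole_post_rate
            if not is_th.any():
                is_th[int(rng.integers(n_posts))] = True
            for j in range(n_posts):
                if is_th[j]:
                    length = int(rng.poisson(config.post_length_mean_positive)) + 1
                    text = _mix_post(rng, length, blocks["shared"], blocks["th"],
                                     config.treehole_signal_strength)
                    posts.append(Post(text, "tree_hole", _timestamp(rng)))
                    signal_idx.append(j)
                else:
                    length = int(rng.poisson(config.post_length_mean_negative)) + 1
                    text = _mix_post(rng, length, blocks["shared"], blocks["neg"],
                                     config.signal_strength)
                    posts.append(Post(text, "ordinary", _timestamp(rng)))
        else:
            n_posts = int(rng.poisson(config.posts_per_user_mean_positive)) + 1
            is_th = rng.random(n_posts) < config.treehole_post_rate
            if not is_th.any():
                is_th[int(rng.integers(n_posts))] = True
            for j in range(n_posts):
                length = int(rng.poisson(config.post_length_mean_positive)) + 1
                if is_th[j]:
                    text = _mix_post(rng, length, blocks["shared"], blocks["th"],
                                     config.treehole_signal_strength)
                    posts.append(Post(text, "tree_hole", _timestamp(rng)))
                else:
                    text = _mix_post(rng, length, blocks["shared"], blocks["pos"],
                                     config.signal_strength)
                    posts.append(Post(text, "ordinary", _timestamp(rng)))
                signal_idx.append(j)
        users.append(UserRecord(uid, posts, "suicidal"))
        truth.users[uid] = UserTruth("suicidal", hidden, signal_idx)

    n_amb = int(round(config.ambiguous_negative_fraction * config.n_negative))
    amb_flags = np.zeros(config.n_negative, dtype=bool)
    amb_flags[rng.choice(config.n_negative, size=n_amb, replace=False)] = True

    for i in range(config.n_negative):
        uid = f"neg_u{i:04d}"
        ambiguous = bool(amb_flags[i])
        n_posts = int(rng.poisson(config.posts_per_user_mean_negative)) + 1
        posts = []
        for _ in range(n_posts):
            length = int(rng.poisson(config.post_length_mean_negative)) + 1
            toks = []
            for _t in range(length):
                u01 = rng.random()
                if ambiguous and u01 < config.ambiguous_signal_strength:
                    # dark lyrics / complaint vocabulary overlapping the
                    # positive class (including overt disclosure words,
                    # quoted without the label)
                    block = blocks["pos"] if rng.random() < 0.5 else blocks["th"]
                    toks.append(block[rng.integers(len(block))])
                elif u01 < config.ambiguous_signal_strength + config.signal_strength:
                    toks.append(blocks["neg"][rng.integers(len(blocks["neg"]))])
                else:
                    toks.append(blocks["shared"][rng.integers(len(blocks["shared"]))])
            posts.append(Post(" ".join(toks), "ordinary", _timestamp(rng)))
        users.append(UserRecord(uid, posts, "non_suicidal"))
        truth.users[uid] = UserTruth("non_suicidal", False, [], ambiguous)

    return Corpus(users, name=f"synthetic-seed{config.seed}"), truth


# ---------------------------------------------------------------------------
# dirty corpora for exercising the cleaning pipeline
# ---------------------------------------------------------------------------

@dataclass
class NoiseSpec:
    """Per-post injection rates for each kind of removable noise."""

    url_rate: float = 0.1
    mention_rate: float = 0.1
    emoticon_rate: float = 0.1
    boilerplate_rate: float = 0.05
    location_rate: float = 0.05
    supertopic_rate: float = 0.05
    system_post_rate: float = 0.05  # chance of inserting a system post after each post
    url_only_post_rate: float = 0.02  # posts that clean down to empty residue

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class InjectionLedger:
    """Exact counts of injected noise, for verifying cleaning tallies."""

    strips: dict[str, int] = field(default_factory=dict)
    system_posts: int = 0
    url_only_posts: int = 0

    def bump(self, rule: str, n: int = 1) -> None:
        self.strips[rule] = self.strips.get(rule, 0) + n


_NOISE_TOKENS = {
    "url": "http://t.cn/x{k}",
    "mention": "@user{k}",
    "emoticon": "[smile]",
    "boilerplate": "sharing pictures",
    "location": "Beijing",
    "supertopic": "#topic{k}#",
}


def generate_dirty_corpus(
    config: GeneratorConfig, noise: NoiseSpec | None = None
) -> tuple[Corpus, InjectionLedger]:
    """A generated corpus with removable noise injected at known rates.

    Noise tokens are inserted at random positions inside posts; system
    posts and URL-only posts are inserted as whole posts.  The returned
    ledger counts every injection so cleaning tallies can be checked
    exactly.  With all rates zero the output equals ``generate_corpus``'s.
    """
    noise = noise or NoiseSpec()
    corpus, _ = generate_corpus(config)
    rng = np.random.default_rng((config.seed + 777) % (2**31 - 1))
    ledger = InjectionLedger()
    k = 0
    users = []
    for u in corpus.users:
        posts = []
        for p in u.posts:
            toks = p.text.split()
            for rule in ("url", "mention", "emoticon", "boilerplate",
                         "location", "supertopic"):
                if rng.random() < getattr(noise, f"{rule}_rate"):
                    token = _NOISE_TOKENS[rule].format(k=k)
                    k += 1
                    toks.insert(int(rng.integers(len(toks) + 1)), token)
                    ledger.bump(rule)
            posts.append(Post(" ".join(toks), p.source, p.created_at))
            if rng.random() < noise.system_post_rate:
                posts.append(Post("Auto-generated check-in message", "system", None))
                ledger.system_posts += 1
            if rng.random() < noise.url_only_post_rate:
                token = _NOISE_TOKENS["url"].format(k=k)
                k += 1
                posts.append(Post(token, p.source if p.source != "system" else "ordinary",
                                  None))
                ledger.bump("url")
                ledger.url_only_posts += 1
        users.append(UserRecord(u.user_id, posts, u.label))
    return Corpus(users, name=corpus.name + ":dirty"), ledger
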