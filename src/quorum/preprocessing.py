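"""Post cleaning and the sentence-level mask.

Cleaning applies an ordered rule pipeline to every post: platform-generated
("system") posts are dropped outright; URLs, @-mentions, emoticon tokens,
boilerplate phrases, listed location strings and SuperTopic titles are
stripped from the text; posts whose residue is empty are dropped; finally,
users left with too few posts are removed from the corpus.  Rules are applied
to a fixed point, so cleaning is idempotent by construction.

The sentence-level mask deletes every post whose provenance tag is in the
masked set (by default the tree-hole tag).  Masking operates on provenance
only, never on content: it reproduces the harder "masked" condition in which
a user's overt disclosures are unavailable and the classifier must rely on
the ordinary timeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

from .corpus import Corpus, CorpusError, Post, UserRecord

# Rule names, in application order.  A post removed by an earlier rule is not
# seen by later rules.
RULES = (
    "system",
    "url",
    "mention",
    "emoticon",
    "boilerplate",
    "location",
    "supertopic",
    "empty_residue",
    "min_posts",
)

_DEFAULT_URL = r"(?:https?://\S+|t\.cn/\S+)"
_DEFAULT_MENTION = r"@\S+"
# bracketed emoticon shortcodes like [笑cry] plus Unicode emoji planes
_DEFAULT_EMOTICON = r"(?:\[[^\[\]\s]{1,12}\]|[\U0001F000-\U0001FAFF☀-➿️])"
_DEFAULT_SUPERTOPIC = r"#[^#]+#"
_DEFAULT_BOILERPLATE = ("分享图片", "sharing pictures", "分享视频", "网页链接")
_DEFAULT_LOCATIONS = ("北京", "上海", "广州", "Beijing", "Shanghai")


@dataclass
class CleaningConfig:
    """Patterns and thresholds for the post-cleaning pipeline.

    All regex sources and term lists are overridable: the default inventories
    are placeholders of the right shape, not a faithful reconstruction of any
    platform's emoticon set or administrative-division gazetteer.
    """

    url_pattern: str = _DEFAULT_URL
    mention_pattern: str = _DEFAULT_MENTION
    emoticon_pattern: str = _DEFAULT_EMOTICON
    boilerplate_phrases: tuple[str, ...] = _DEFAULT_BOILERPLATE
    location_list: tuple[str, ...] = _DEFAULT_LOCATIONS
    supertopic_pattern: str = _DEFAULT_SUPERTOPIC
    min_posts_per_user: int = 3

    def __post_init__(self) -> None:
        if self.min_posts_per_user < 1:
            raise ValueError("min_posts_per_user must be >= 1")
        for src in (self.url_pattern, self.mention_pattern,
                    self.emoticon_pattern, self.supertopic_pattern):
            re.compile(src)  # raises re.error on a bad pattern

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CleaningConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "location_file" in data:
            loc_path = Path(data.pop("location_file"))
            terms = [t.strip() for t in loc_path.read_text(encoding="utf-8").splitlines()]
            data["location_list"] = tuple(t for t in terms if t)
        for key in ("boilerplate_phrases", "location_list"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class MaskConfig:
    """Which provenance tags the sentence-level mask deletes."""

    masked_sources: frozenset[str] = frozenset({"tree_hole"})

    def __post_init__(self) -> None:
        self.masked_sources = frozenset(self.masked_sources)
        if not self.masked_sources:
            raise ValueError("masked_sources must be nonempty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MaskConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "masked_sources" in data:
            data["masked_sources"] = frozenset(data["masked_sources"])
        return cls(**data)


@dataclass
class RemovalTally:
    """Per-rule counts of removed matches, posts and users."""

    strips: dict[str, int] = field(default_factory=dict)
    posts_removed: dict[str, int] = field(default_factory=dict)
    users_removed: dict[str, int] = field(default_factory=dict)

    def bump(self, counter: dict[str, int], rule: str, n: int = 1) -> None:
        if n:
            counter[rule] = counter.get(rule, 0) + n

    def to_tsv(self, path: str | Path) -> None:
        observed = [r for r in (*self.strips, *self.posts_removed, *self.users_removed)
                    if r not in RULES]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("rule\tmatches_stripped\tposts_removed\tusers_removed\n")
            for rule in (*RULES, *dict.fromkeys(observed)):
                fh.write(
                    f"{rule}\t{self.strips.get(rule, 0)}\t"
                    f"{self.posts_removed.get(rule, 0)}\t{self.users_removed.get(rule, 0)}\n"
                )


_WS = re.compile(r"\s+")


def _strip_once(text: str, config: CleaningConfig, counts: dict[str, int]) -> str:
    def sub(rule: str, pattern: str, s: str) -> str:
        s, n = re.subn(pattern, " ", s)
        counts[rule] = counts.get(rule, 0) + n
        return s

    text = sub("url", config.url_pattern, text)
    text = sub("mention", config.mention_pattern, text)
    text = sub("emoticon", config.emoticon_pattern, text)
    for phrase in config.boilerplate_phrases:
        n = text.count(phrase)
        if n:
            counts["boilerplate"] = counts.get("boilerplate", 0) + n
            text = text.replace(phrase, " ")
    for loc in config.location_list:
        n = text.count(loc)
        if n:
            counts["location"] = counts.get("location", 0) + n
            text = text.replace(loc, " ")
    text = sub("supertopic", config.supertopic_pattern, text)
    return _WS.sub(" ", text).strip()


def _clean_text(text: str, config: CleaningConfig, counts: dict[str, int]) -> str:
    # iterate to a fixed point so substring removal can never leave a new
    # match behind (guarantees idempotence of the whole pipeline)
    for _ in range(32):
        new = _strip_once(text, config, counts)
        if new == text:
            return text
        text = new
    return text


def clean_post(post: Post, config: CleaningConfig | None = None) -> Post | None:
    """Apply the per-post cleaning rules; ``None`` means the post is removed.

    System-generated posts are removed outright; otherwise URLs, mentions,
    emoticons, boilerplate, locations and SuperTopic titles are stripped and
    the post is removed if nothing non-whitespace remains.  Idempotent.
    """
    cleaned, _rule, _counts = _clean_post_traced(post, config or CleaningConfig())
    return cleaned


def _clean_post_traced(
    post: Post, config: CleaningConfig
) -> tuple[Post | None, str | None, dict[str, int]]:
    counts: dict[str, int] = {}
    if post.source == "system":
        return None, "system", counts
    text = _clean_text(post.text, config, counts)
    if not text:
        return None, "empty_residue", counts
    if text == post.text:
        return post, None, counts
    return Post(text, post.source, post.created_at), None, counts


def clean_corpus(
    corpus: Corpus, config: CleaningConfig | None = None
) -> tuple[Corpus, RemovalTally]:
    """Clean every post and drop users left with too few posts.

    Returns the cleaned corpus together with a :class:`RemovalTally`
    recording, per rule, how many text matches were stripped, how many posts
    were removed, and how many users were dropped.
    """
    config = config or CleaningConfig()
    tally = RemovalTally()
    users: list[UserRecord] = []
    for u in corpus.users:
        kept: list[Post] = []
        for p in u.posts:
            cleaned, rule, counts = _clean_post_traced(p, config)
            for r, n in counts.items():
                tally.bump(tally.strips, r, n)
            if cleaned is None:
                tally.bump(tally.posts_removed, rule)
            else:
                kept.append(cleaned)
        if len(kept) < config.min_posts_per_user:
            tally.bump(tally.users_removed, "min_posts")
        else:
            users.append(UserRecord(u.user_id, kept, u.label))
    return Corpus(users, name=corpus.name), tally


def apply_sentence_mask(
    corpus: Corpus, mask: MaskConfig | None = None
) -> tuple[Corpus, RemovalTally]:
    """Delete every post whose source is in the masked set.

    User order and remaining-post order are preserved; users reduced to zero
    posts are dropped and reported in the tally.  Idempotent, and never
    increases any user's post count.
    """
    mask = mask or MaskConfig()
    for src in mask.masked_sources:
        if src not in ("tree_hole", "ordinary", "system"):
            raise CorpusError(f"unknown source {src!r} in mask config")
    tally = RemovalTally()
    users: list[UserRecord] = []
    for u in corpus.users:
        kept = [p for p in u.posts if p.source not in mask.masked_sources]
        n_removed = len(u.posts) - len(kept)
        tally.bump(tally.posts_removed, "masked_source", n_removed)
        if kept:
            users.append(UserRecord(u.user_id, kept, u.label))
        else:
            tally.bump(tally.users_removed, "masked_source")
    return Corpus(users, name=corpus.name), tally


def mask_post_counts(corpus: Corpus, mask: MaskConfig | None = None) -> dict[str, int]:
    """Number of posts per user that the mask would delete (diagnostic)."""
    mask = mask or MaskConfig()
    return {
        u.user_id: sum(1 for p in u.posts if p.source in mask.masked_sources)
        for u in corpus.users
    }
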