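"""Tweet normalization with special-token markers, and fixed-size chunking.

Normalization marks three informal-text habits with lowercase angle-bracket
tokens, emitted as separate whitespace-delimited words:

* ``<allcaps>``   after a fully capitalized word (>= 2 letters), which is
  rewritten in sentence case ("YES" -> "Yes <allcaps>");
* ``<elongated>`` after a word whose letters were repeated >= 3 times
  ("soooo" -> "so <elongated>") and after a run of repeated terminal
  punctuation, which is collapsed to a single mark ("much!!!" ->
  "much! <elongated>");
* ``<repeated>``  after a run of consecutive duplicate words, collapsed to
  one occurrence ("so so" -> "so <repeated>").

Chunking greedily concatenates a user's tweets in time order until adding
the next tweet would exceed the word budget (default 250 words, counting
markers); every tweet lands in exactly one chunk. In monitoring mode each
chunk is dated by its middle tweet.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from datetime import date

import numpy as np

from .records import Tweet, UserRecord

MARKER_ALLCAPS = "<allcaps>"
MARKER_ELONGATED = "<elongated>"
MARKER_REPEATED = "<repeated>"
MARKERS = (MARKER_ALLCAPS, MARKER_ELONGATED, MARKER_REPEATED)

_MARKER_TOKEN = re.compile(r"<(?:allcaps|elongated|repeated)>\W*")
_ELONGATION = re.compile(r"(\w)\1{2,}")
_PUNCT = set(string.punctuation)


def _split_punct(token: str) -> tuple[str, str, str]:
    """(leading punctuation, core, trailing punctuation)."""
    i, j = 0, len(token)
    while i < j and token[i] in _PUNCT:
        i += 1
    while j > i and token[j - 1] in _PUNCT:
        j -= 1
    return token[:i], token[i:j], token[j:]


def normalize_tweet(text: str) -> str:
    out: list[str] = []
    prev_core: str | None = None
    run_marked = False
    for token in text.split():
        if _MARKER_TOKEN.fullmatch(token):
            out.append(token)  # already-normalized marker: pass through
            continue
        prefix, core, suffix = _split_punct(token)
        if not core:
            # pure punctuation token; collapse a run of one repeated mark
            if len(token) >= 2 and len(set(token)) == 1:
                out.extend([token[0], MARKER_ELONGATED])
            else:
                out.append(token)
            prev_core = None
            continue

        elongated = bool(_ELONGATION.search(core))
        if elongated:
            core = _ELONGATION.sub(r"\1", core)
        allcaps = core.isupper() and sum(c.isalpha() for c in core) >= 2
        if allcaps:
            core = core.capitalize()

        key = core.lower()
        if key == prev_core:
            if not run_marked:
                out.append(MARKER_REPEATED)
                run_marked = True
            continue
        prev_core, run_marked = key, False

        parts = [prefix + core]
        if allcaps:
            parts.append(MARKER_ALLCAPS)
        if elongated:
            parts.append(MARKER_ELONGATED)
        if len(suffix) >= 2 and len(set(suffix)) == 1:
            parts[-1] += suffix[0]
            parts.append(MARKER_ELONGATED)
        elif suffix:
            parts[-1] += suffix
        out.extend(parts)
    return " ".join(out)


@dataclass
class TweetChunk:
    chunk_id: str
    user_id: str
    label: str
    text: str
    word_count: int
    tweet_ids: list[str] = field(default_factory=list)
    chunk_date: date | None = None

    def to_dict(self) -> dict:
        d = {
            "chunk_id": self.chunk_id,
            "user_id": self.user_id,
            "label": self.label,
            "text": self.text,
            "word_count": self.word_count,
            "tweet_ids": list(self.tweet_ids),
        }
        if self.chunk_date is not None:
            d["chunk_date"] = self.chunk_date.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TweetChunk":
        cd = d.get("chunk_date")
        return cls(d["chunk_id"], d["user_id"], d["label"], d["text"],
                   d["word_count"], list(d["tweet_ids"]),
                   date.fromisoformat(cd) if cd else None)


def build_chunks(user: UserRecord, max_words: int = 250,
                 mode: str = "classification", normalize: bool = True,
                 drop_partial: bool = False) -> list[TweetChunk]:
    """Greedy assembly of consecutive tweets into <= max_words chunks.

    A single tweet longer than the budget forms its own oversize chunk
    (tweets are never split). In monitoring mode the chunk date is the date
    of the middle tweet, index floor(k/2) of the k tweets in the chunk.
    In classification mode a trailing partial chunk is kept unless
    ``drop_partial`` is set.
    """
    if max_words < 1:
        raise ValueError("max_words must be >= 1")
    if mode not in ("classification", "monitoring"):
        raise ValueError(f"unknown mode {mode!r}")
    tweets = sorted(user.tweets, key=lambda t: t.timestamp)

    chunks: list[TweetChunk] = []
    cur: list[tuple[Tweet, str, int]] = []
    cur_wc = 0

    def close() -> None:
        nonlocal cur, cur_wc
        if not cur:
            return
        idx = len(chunks)
        members = [t for t, _, _ in cur]
        chunk = TweetChunk(
            chunk_id=f"{user.user_id}_c{idx:04d}",
            user_id=user.user_id,
            label=user.group,
            text=" ".join(txt for _, txt, _ in cur),
            word_count=cur_wc,
            tweet_ids=[t.tweet_id for t in members],
            chunk_date=(members[len(members) // 2].timestamp.date()
                        if mode == "monitoring" else None),
        )
        chunks.append(chunk)
        cur, cur_wc = [], 0

    for tweet in tweets:
        text = normalize_tweet(tweet.text) if normalize else tweet.text
        wc = len(text.split())
        if cur and cur_wc + wc > max_words:
            close()
        cur.append((tweet, text, wc))
        cur_wc += wc
        if cur_wc >= max_words:
            close()
    if cur and not (drop_partial and mode == "classification"):
        close()
    return chunks


def chunk_corpus(users: list[UserRecord], max_words: int = 250,
                 mode: str = "classification",
                 identifying_ids: set[str] | None = None,
                 **kwargs) -> list[TweetChunk]:
    """Chunk every user, optionally dropping identifying tweets first."""
    out = []
    for user in users:
        if identifying_ids:
            user = UserRecord(user.user_id, user.group, user.description,
                              user.personality, user.gender, user.age_bin,
                              drop_identifying(user.tweets, identifying_ids))
        out.extend(build_chunks(user, max_words=max_words, mode=mode, **kwargs))
    return out


def drop_identifying(items: list, identifying_tweet_ids: set[str] | list[str]):
    """Remove identifying tweets (by tweet_id) or chunks containing them."""
    ids = set(identifying_tweet_ids)
    if not items:
        return list(items)
    if isinstance(items[0], TweetChunk):
        return [c for c in items if not ids.intersection(c.tweet_ids)]
    return [t for t in items if t.tweet_id not in ids]


@dataclass
class SplitAssignment:
    test_ids: list[str]
    train_sets: dict[int, list[str]]  # size -> user ids (nested)

    def to_dict(self) -> dict:
        return {"test_ids": self.test_ids,
                "train_sets": {str(k): v for k, v in self.train_sets.items()}}


def stratified_split(users: list[UserRecord], test_n: int = 500,
                     train_sizes: list[int | None] | None = None,
                     seed: int = 0) -> SplitAssignment:
    """User-level stratified split: a 1:1 balanced test set of ``test_n``
    users, then nested 1:1 balanced training sets of the requested sizes
    (None = all remaining, floored to a balanced count)."""
    if test_n % 2:
        raise ValueError("test_n must be even for a 1:1 ratio")
    by_group: dict[str, list[str]] = {}
    for u in users:
        by_group.setdefault(u.group, []).append(u.user_id)
    if len(by_group) != 2:
        raise ValueError(f"need two groups, got {sorted(by_group)}")
    rng = np.random.default_rng(seed)
    pools = {}
    for g, ids in by_group.items():
        ids = sorted(ids)
        rng.shuffle(ids)
        pools[g] = ids

    half = test_n // 2
    sizes_avail = {g: len(v) for g, v in pools.items()}
    if any(len(v) < half for v in pools.values()):
        raise ValueError(f"insufficient users for test set: available {sizes_avail}")
    test_ids = sorted(pools[g][i] for g in pools for i in range(half))
    remain = {g: v[half:] for g, v in pools.items()}

    max_train = 2 * min(len(v) for v in remain.values())
    train_sizes = train_sizes if train_sizes is not None else [max_train]
    resolved = sorted({(max_train if s is None else int(s)) for s in train_sizes})
    train_sets: dict[int, list[str]] = {}
    for s in resolved:
        if s % 2:
            raise ValueError("train sizes must be even for a 1:1 ratio")
        if s > max_train:
            raise ValueError(
                f"train size {s} exceeds available balanced pool {max_train} "
                f"(remaining per group: { {g: len(v) for g, v in remain.items()} })")
        train_sets[s] = sorted(remain[g][i] for g in remain for i in range(s // 2))
    return SplitAssignment(test_ids, train_sets)
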